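import numpy as np
import pandas as pd
import pytest

from cuniqg.pedigree import Pedigree
from cuniqg.mixed_model import (Channel, ModelError, ModelSpec, RandomTerm,
                                TraitSpec, build_design, nba_spec, reml_fit,
                                stepwise_select, wald_f_test, ww_spec)
from cuniqg.simulate import PhenotypeTable, SimulationConfig, \
    simulate_population


def unrelated_pedigree(ids):
    n = len(ids)
    return Pedigree(ids=np.array(ids, dtype=object), sire=np.full(n, -1),
                    dam=np.full(n, -1), sex=np.array(["M"] * n, dtype=object))


def half_sib_data(s=30, n=20, var_s=2.0, var_e=5.0, seed=1):
    rng = np.random.default_rng(seed)
    sire = np.repeat(np.arange(s), n)
    y = (np.sqrt(var_s) * rng.standard_normal(s)[sire]
         + rng.normal(0, np.sqrt(var_e), s * n))
    animals = pd.DataFrame({
        "animal_id": [f"a{i}" for i in range(s * n)],
        "sire": [f"s{j}" for j in sire],
        "y": y,
    })
    pheno = PhenotypeTable(animals=animals, litters=pd.DataFrame())
    ped = unrelated_pedigree(animals.animal_id)
    spec = ModelSpec(
        traits=[TraitSpec(name="y", response="y", fixed=[])],
        random=[RandomTerm("sire", "iid", [Channel("y", "sire")])],
    )
    return spec, ped, pheno, y.reshape(s, n)


class TestLinearReml:
    def test_matches_balanced_anova(self):
        spec, ped, pheno, ymat = half_sib_data()
        fit = reml_fit(build_design(spec, ped, pheno))
        s, n = ymat.shape
        ybar = ymat.mean(1)
        msb = n * np.var(ybar, ddof=1)
        msw = np.sum((ymat - ybar[:, None]) ** 2) / (s * (n - 1))
        assert fit.converged
        assert fit.varcomp.terms["sire"][1][0, 0] == pytest.approx(
            (msb - msw) / n, abs=1e-6
        )
        assert fit.varcomp.residual[0, 0] == pytest.approx(msw, abs=1e-6)

    def test_constant_response_hits_boundary(self):
        spec, ped, pheno, _ = half_sib_data(s=10, n=5)
        pheno.animals["y"] = 3.14
        fit = reml_fit(build_design(spec, ped, pheno))
        assert fit.varcomp.terms["sire"][1][0, 0] <= 1e-6

    def test_blup_solutions_satisfy_mme(self):
        spec, ped, pheno, _ = half_sib_data(s=15, n=8, seed=3)
        design = build_design(spec, ped, pheno)
        fit = reml_fit(design)
        from cuniqg.mixed_model import _MME, _ParamMap

        pmap = _ParamMap(design)
        mats, R = pmap.to_mats(pmap.from_mats(
            [fit.varcomp.terms["sire"][1]], fit.varcomp.residual))
        mme = _MME(design, mats, R)
        resid = mme.C @ mme.sol - mme.rhs
        rel = np.linalg.norm(resid) / np.linalg.norm(mme.rhs)
        assert rel < 1e-8

    def test_optimum_beats_random_perturbations(self):
        spec, ped, pheno, _ = half_sib_data(s=20, n=10, seed=5)
        design = build_design(spec, ped, pheno)
        fit = reml_fit(design)
        from cuniqg.mixed_model import _ParamMap, _neg2ll

        pmap = _ParamMap(design)
        theta_hat = pmap.from_mats([fit.varcomp.terms["sire"][1]],
                                   fit.varcomp.residual)
        ll_hat = -0.5 * _neg2ll(design, pmap, theta_hat, None)[0]
        rng = np.random.default_rng(0)
        for _ in range(50):
            pert = theta_hat * np.exp(rng.normal(0, 0.2, pmap.n))
            ll = -0.5 * _neg2ll(design, pmap, pert, None)[0]
            assert ll <= ll_hat + 1e-7

    def test_animal_model_recovers_nba_truth(self):
        """Litter-size variance recovery at the study's nucleus scale."""
        truth = 1.71
        est = []
        for rep in range(6):
            cfg = SimulationConfig(
                n_sires=35, n_dams=140, litters_per_dam=5, kits_per_litter=1,
                n_batches=10, seed=300 + rep, disease={}, composite=(),
                ww=None,
            )
            ped, pheno, _ = simulate_population(cfg)
            fit = reml_fit(build_design(nba_spec(), ped, pheno))
            assert fit.converged
            est.append(fit.varcomp.terms["additive"][1][0, 0])
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - truth) < 3 * se + 0.15


class TestDesign:
    def test_sex_only_design_columns(self):
        animals = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(10)],
            "sex": ["M", "F"] * 5,
            "y": np.arange(10.0),
        })
        ped = unrelated_pedigree(animals.animal_id)
        spec = ModelSpec(
            traits=[TraitSpec(name="y", response="y", fixed=["sex"])],
            random=[],
        )
        d = build_design(spec, ped, PhenotypeTable(animals, pd.DataFrame()))
        # intercept + one column under reference (corner) coding
        assert d.X.shape == (10, 2)

    def test_batch_levels_become_columns(self, small_population):
        _, ped, pheno, _ = small_population
        n_batches = pheno.animals.batch.nunique()
        spec = ModelSpec(
            traits=[TraitSpec(name="WW", response="WW", fixed=["batch"])],
            random=[],
        )
        d = build_design(spec, ped, pheno)
        a, b = d.fixed_cols[("WW", "batch")]
        assert b - a == n_batches - 1   # corner constraint absorbs one

    def test_fostered_kit_uses_adoptive_dam_columns(self):
        animals = pd.DataFrame({
            "animal_id": ["K1", "K2"],
            "dam_id": ["D1", "D1"],
            "rearing_dam_id": ["D2", "D1"],   # K1 fostered to D2
            "litter": ["L2", "L1"],
            "WW": [500.0, 600.0],
        })
        ped_df = pd.DataFrame({
            "animal_id": ["S1", "D1", "D2", "K1", "K2"],
            "sire_id": ["0", "0", "0", "S1", "S1"],
            "dam_id": ["0", "0", "0", "D1", "D1"],
            "sex": ["M", "F", "F", "M", "M"],
        })
        from cuniqg.pedigree import pedigree_from_frame

        ped = pedigree_from_frame(ped_df)
        spec = ww_spec(fixed=())
        d = build_design(spec, ped, PhenotypeTable(animals, pd.DataFrame()))
        Z_maternal = d.Zc[0][1].toarray()   # additive term, maternal channel
        k1_row = Z_maternal[0]
        assert k1_row[ped.index_of("D2")] == 1.0
        assert k1_row[ped.index_of("D1")] == 0.0
        # direct channel still follows the biological animal itself
        Z_direct = d.Zc[0][0].toarray()
        assert Z_direct[0, ped.index_of("K1")] == 1.0

    def test_missing_factor_is_reported(self):
        animals = pd.DataFrame({"animal_id": ["a"], "y": [1.0]})
        ped = unrelated_pedigree(["a"])
        spec = ModelSpec(
            traits=[TraitSpec(name="y", response="y", fixed=["nothere"])],
            random=[],
        )
        with pytest.raises(ModelError, match="nothere"):
            build_design(spec, ped, PhenotypeTable(animals, pd.DataFrame()))


def oneway_data(k=4, n=12, effects=None, seed=0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(k), n)
    mu = np.zeros(k) if effects is None else np.asarray(effects)
    y = mu[g] + rng.standard_normal(k * n)
    animals = pd.DataFrame({
        "animal_id": [f"a{i}" for i in range(k * n)],
        "grp": [f"g{j}" for j in g],
        "y": y,
    })
    spec = ModelSpec(
        traits=[TraitSpec(name="y", response="y", fixed=["grp"])],
        random=[],
    )
    return spec, unrelated_pedigree(animals.animal_id), \
        PhenotypeTable(animals, pd.DataFrame()), y.reshape(k, n)


class TestWaldF:
    def test_equals_classical_anova_f(self):
        spec, ped, pheno, ymat = oneway_data(seed=8)
        fit = reml_fit(build_design(spec, ped, pheno))
        F, q, ddf, p = wald_f_test(fit, "y", "grp")
        from scipy.stats import f_oneway

        F_ref, p_ref = f_oneway(*list(ymat))
        assert q == ymat.shape[0] - 1
        assert F == pytest.approx(F_ref, abs=1e-8)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_zero_for_equal_group_means(self):
        spec, ped, pheno, _ = oneway_data()
        pheno.animals["y"] = np.tile([1.0, 2.0], len(pheno.animals) // 2)
        # identical composition per group: group means equal, noiseless
        fit = reml_fit(build_design(spec, ped, pheno))
        F, *_ = wald_f_test(fit, "y", "grp")
        assert F == pytest.approx(0.0, abs=1e-10)

    def test_type_one_error_rate(self):
        rejections = 0
        n_rep = 500
        for rep in range(n_rep):
            spec, ped, pheno, _ = oneway_data(k=3, n=8, seed=1000 + rep)
            fit = reml_fit(build_design(spec, ped, pheno))
            _, _, _, p = wald_f_test(fit, "y", "grp")
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestStepwise:
    def test_empty_candidate_list_is_unchanged(self):
        spec, ped, pheno, _ = oneway_data()
        spec.traits[0].fixed = []
        out = stepwise_select(spec, ped, pheno)
        assert out.traits[0].fixed == []

    def test_strong_factor_always_retained(self):
        for rep in range(20):
            spec, ped, pheno, _ = oneway_data(
                k=3, n=10, effects=[0.0, 2.0, 4.0], seed=2000 + rep
            )
            out = stepwise_select(spec, ped, pheno, alpha=0.05)
            assert out.traits[0].fixed == ["grp"]

    def test_null_factor_retention_near_alpha(self):
        kept = 0
        n_rep = 120
        for rep in range(n_rep):
            spec, ped, pheno, _ = oneway_data(k=3, n=8, seed=5000 + rep)
            out = stepwise_select(spec, ped, pheno, alpha=0.05)
            kept += bool(out.traits[0].fixed)
        rate = kept / n_rep
        assert rate < 0.12          # ~alpha-level false retention


class TestMultiTrait:
    @staticmethod
    def bivariate_data(seed, rg=0.0, n_sires=60, n_prog=10):
        cov = np.array([[1.0, rg], [rg, 1.0]])
        rng = np.random.default_rng(seed)
        u = rng.multivariate_normal([0, 0], 0.5 * cov, n_sires)
        sire = np.repeat(np.arange(n_sires), n_prog)
        e = rng.multivariate_normal([0, 0], np.diag([2.0, 2.0]),
                                    n_sires * n_prog)
        y = u[sire] + e
        animals = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(len(sire))],
            "sire": [f"s{j}" for j in sire],
            "y1": y[:, 0], "y2": y[:, 1],
        })
        spec = ModelSpec(
            traits=[TraitSpec(name="t1", response="y1", fixed=[]),
                    TraitSpec(name="t2", response="y2", fixed=[])],
            random=[RandomTerm("sire", "iid",
                               [Channel("t1", "sire"),
                                Channel("t2", "sire")])],
        )
        return spec, unrelated_pedigree(animals.animal_id), \
            PhenotypeTable(animals, pd.DataFrame())

    def test_zero_genetic_correlation_coverage(self):
        """r_g estimates for truth 0 stay within 2 SE of 0 on average."""
        rs = []
        for rep in range(12):
            spec, ped, pheno = self.bivariate_data(100 + rep, rg=0.0)
            fit = reml_fit(build_design(spec, ped, pheno))
            (_, mat) = fit.varcomp.terms["sire"]
            r = mat[0, 1] / np.sqrt(mat[0, 0] * mat[1, 1])
            rs.append(r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 2 * se + 0.05

    def test_cross_environment_residual_fixed_at_zero(self):
        cfg = SimulationConfig(
            n_sires=40, n_dams=120, litters_per_dam=1, kits_per_litter=6,
            n_batches=4, seed=31, ww=None, nba=None, composite=(),
            disease={"Dig": __import__("cuniqg").DiseaseTraitParams(
                0.4, 0.4, 0.1, 0.1, r_g_env=0.6,
                prevalence_S=0.3, prevalence_Ch=0.4)},
        )
        ped, pheno, _ = simulate_population(cfg)
        from cuniqg.mixed_model import bivariate_cross_env_spec

        spec = bivariate_cross_env_spec("Dig", fixed=())
        d = build_design(spec, ped, pheno)
        # disjoint recording: the off-diagonal residual is not estimable
        assert not d.resid_free[0, 1]
        fit = reml_fit(d)
        assert fit.varcomp.residual[0, 1] == 0.0
        assert fit.converged
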