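import math

import numpy as np
import pytest

from cuniqg.simulate import (DiseaseTraitParams, SimulationConfig,
                             expected_composite_prevalence,
                             expected_prevalence, marginal_prevalence,
                             simulate_population, solve_intercept,
                             write_population)


def test_inverse_link_identities():
    # zero variances: marginal prevalence is the inverse link itself
    assert marginal_prevalence(0.0, 0.0, "logit") == pytest.approx(0.5)
    mu = math.log(0.26 / 0.74)
    assert marginal_prevalence(mu, 0.0, "logit") == pytest.approx(0.26)
    assert marginal_prevalence(0.0, 0.0, "probit") == pytest.approx(0.5)


def test_solve_intercept_round_trip():
    for var in (0.0, 0.3, 1.2):
        for p in (0.1, 0.41, 0.8):
            mu = solve_intercept(p, var, "logit")
            assert marginal_prevalence(mu, var, "logit") == pytest.approx(p)


def test_expected_prevalence_against_monte_carlo():
    # disorder with additive 0.29 and litter 0.01 on the logit scale
    params = DiseaseTraitParams(0.29, 0.29, 0.01, 0.01,
                                prevalence_Ch=0.41)
    p_quad = expected_prevalence(params, "Ch")
    rng = np.random.default_rng(4)
    n = 1_000_000
    mu = solve_intercept(0.41, 0.30, "logit")
    liab = mu + rng.normal(0, math.sqrt(0.30), n) + rng.logistic(0, 1, n)
    p_mc = (liab > 0).mean()
    assert abs(p_quad - p_mc) < 0.003


def test_zero_variance_population_has_constant_liability():
    cfg = SimulationConfig(
        n_sires=5, n_dams=10, litters_per_dam=1, kits_per_litter=4,
        n_batches=2, fraction_batches_to_ch=0.0, seed=0,
        disease={"Resist": DiseaseTraitParams(0, 0, 0, 0,
                                              prevalence_S=0.999)},
        composite=(), ww=None, nba=None,
    )
    cfg.fixed.batch_sd = 0.0
    cfg.fixed.sex_effect_disease = 0.0
    ped, pheno, tv = simulate_population(cfg)
    assert np.abs(tv[["Resist_S", "Resist_Ch"]].to_numpy()).max() < 1e-4
    # prevalence target ~1 with no variation: every kit affected
    assert pheno.animals.Resist.mean() == pytest.approx(1.0, abs=0.05)


def test_default_prevalence_targets():
    """OR-composite hits the configured 26% (S) / 41% (Ch) marginals."""
    cfg = SimulationConfig(n_sires=60, n_dams=300, litters_per_dam=3,
                           kits_per_litter=6, n_batches=10, seed=11,
                           ww=None, nba=None)
    ped, pheno, tv = simulate_population(cfg)
    for env, target in (("S", 0.26), ("Ch", 0.41)):
        sub = pheno.animals[pheno.animals.environment == env]
        shared = cfg.fixed.batch_sd**2 + (cfg.fixed.farm_sd**2
                                          if env == "Ch" else 0.0)
        sx = cfg.fixed.sex_effect_disease
        expect = expected_composite_prevalence(
            cfg.disease, cfg.composite, env, shared_var=shared,
            sex_offsets=((0.5, sx / 2), (0.5, -sx / 2)),
        )
        se = math.sqrt(target * (1 - target) / len(sub))
        assert abs(expect - target) < 0.01     # intercept solving
        assert abs(sub.Resist.mean() - expect) < 3 * se + 0.01


def test_resist_is_or_of_components(small_population):
    _, _, pheno, _ = small_population
    a = pheno.animals
    assert ((a.Resist == 1) == ((a.Dig + a.Resp + a.Other) > 0)).all()


def test_same_seed_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(n_sires=10, n_dams=30, litters_per_dam=2,
                           kits_per_litter=5, n_batches=4, seed=123)
    for d in ("a", "b"):
        ped, pheno, tv = simulate_population(cfg)
        write_population(ped, pheno, tv, tmp_path / d)
    for f in ("pedigree.csv", "animals.csv", "litters.csv",
              "true_values.csv"):
        assert (tmp_path / "a" / f).read_bytes() == \
            (tmp_path / "b" / f).read_bytes()


def test_offspring_midparent_regression(small_population):
    cfg, ped, pheno, tv = small_population
    bv = tv.set_index("animal_id")
    kits = pheno.animals
    for trait in ("WW_direct", "NBA"):
        child = bv.loc[kits.animal_id, trait].to_numpy()
        mid = 0.5 * (bv.loc[kits.sire_id, trait].to_numpy()
                     + bv.loc[kits.dam_id, trait].to_numpy())
        slope = np.polyfit(mid, child, 1)[0]
        # offspring on mid-parent regression of true BVs is 1
        assert slope == pytest.approx(1.0, abs=0.12)


def test_mendelian_sampling_variance(small_population):
    cfg, ped, pheno, tv = small_population
    bv = tv.set_index("animal_id")
    kits = pheno.animals
    dev = (bv.loc[kits.animal_id, "WW_direct"].to_numpy()
           - 0.5 * (bv.loc[kits.sire_id, "WW_direct"].to_numpy()
                    + bv.loc[kits.dam_id, "WW_direct"].to_numpy()))
    # within-family variance ~ sigma2_a / 2 for non-inbred parents
    target = 0.5 * cfg.ww.sigma2_a
    assert np.var(dev) == pytest.approx(target, rel=0.15)


def test_cross_environment_sire_family_correlation():
    cfg = SimulationConfig(
        n_sires=400, n_dams=1200, litters_per_dam=1, kits_per_litter=4,
        n_batches=4, seed=21, ww=None, nba=None,
        disease={"Dig": DiseaseTraitParams(1.0, 1.0, r_g_env=0.5)},
        composite=(),
    )
    ped, pheno, tv = simulate_population(cfg)
    kits = pheno.animals
    bv = tv.set_index("animal_id")
    fam = bv.loc[kits.animal_id, ["Dig_S", "Dig_Ch"]]
    fam["sire"] = kits.sire_id.to_numpy()
    means = fam.groupby("sire").mean()
    r = np.corrcoef(means.Dig_S, means.Dig_Ch)[0, 1]
    # paternal family means of the two environment expressions
    assert r == pytest.approx(0.5, abs=0.12)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_sires=0)
    with pytest.raises(ValueError):
        SimulationConfig(fostering_rate=1.5)


def test_nonpsd_cross_env_correlation_rejected():
    cfg = SimulationConfig(
        n_sires=5, n_dams=10, litters_per_dam=1, kits_per_litter=2,
        n_batches=2, seed=0, ww=None, nba=None, composite=(),
        disease={"Dig": DiseaseTraitParams(1.0, 1.0, r_g_env=1.2)},
    )
    with pytest.raises(ValueError, match="definite|correlation"):
        simulate_population(cfg)
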