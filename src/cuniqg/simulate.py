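"""Synthetic two-environment rabbit populations.

Generates pedigreed populations with the statistical structure the analysis
assumes: a closed maternal line in which kits from every second weaning batch
(mostly males) are moved to a challenging (Ch) environment after weaning,
disease liabilities with additive, common-litter and logistic residual
components, weaning weight with direct + maternal genetic, common-litter and
maternal environmental components, and repeated litter-size records for does.

The composite "Resist" disorder is the logical OR of digestive signs,
respiratory signs and a latent "other infectious" disorder, so that any
single recorded syndrome marks the animal as affected.

Default parameter values describe a French maternal rabbit line selected for
litter size and weaning weight; see :mod:`cuniqg.presets`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .pedigree import Pedigree, assign_rearing_effects

LOGIT_RESIDUAL = math.pi**2 / 3.0

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass
class DiseaseTraitParams:
    """Liability-scale parameters for one binary disorder, split by environment.

    The S and Ch expressions are distinct genetic traits joined by the
    cross-environment genetic correlation ``r_g_env``; residual is logistic
    (variance pi^2/3) under the logit link, standard normal under probit.
    """

    sigma2_a_S: float
    sigma2_a_Ch: float
    sigma2_litter_S: float = 0.0
    sigma2_litter_Ch: float = 0.0
    r_g_env: float = 1.0
    prevalence_S: float = 0.5
    prevalence_Ch: float = 0.5
    link: str = "logit"

    def sigma2_a(self, env):
        return self.sigma2_a_S if env == "S" else self.sigma2_a_Ch

    def sigma2_litter(self, env):
        return self.sigma2_litter_S if env == "S" else self.sigma2_litter_Ch

    def prevalence(self, env):
        return self.prevalence_S if env == "S" else self.prevalence_Ch


@dataclass
class WeaningWeightParams:
    sigma2_a: float = 2986.0
    sigma2_litter: float = 1218.0
    sigma2_mat_env: float = 730.0
    sigma2_m: float = 474.0
    cov_a_m: float = -842.0       # direct-maternal genetic covariance
    sigma2_e: float = 5620.0
    mean: float = 664.0


@dataclass
class LitterSizeParams:
    sigma2_a: float = 1.71
    sigma2_perm_env: float = 0.32
    sigma2_e: float = 8.47
    mean: float = 9.92


@dataclass
class FixedEffectConfig:
    """Standard deviations of the drawn fixed-effect level values.

    Levels are drawn once per simulation from centered normals, then held
    fixed; their dispersion therefore contributes to marginal prevalences
    and is accounted for in the intercept solver.
    """

    batch_sd: float = 0.25        # liability / trait units per level
    farm_sd: float = 0.30         # Ch farms, disease liabilities only
    sex_effect_disease: float = 0.10   # M minus F liability shift
    sex_effect_ww: float = 20.0        # g
    batch_sd_ww: float = 25.0
    parity_sd_ww: float = 15.0
    year_season_sd_nba: float = 0.4
    parity_status_sd_nba: float = 0.5


@dataclass
class SimulationConfig:
    """Population structure and true parameters for one simulated dataset."""

    n_sires: int = 332
    n_dams: int = 849
    litters_per_dam: int = 5
    kits_per_litter: int = 6
    n_batches: int = 29
    fraction_batches_to_ch: float = 0.5
    p_ch_male: float = 0.97       # P(sent to Ch | male, Ch batch)
    p_ch_female: float = 0.033
    fostering_rate: float = 0.04
    fraction_ww_recorded: float = 0.55
    n_ch_farms: int = 3
    n_base_sires: int | None = None   # grandparental generation (defaults
    n_base_dams: int | None = None    # to a third of the parent counts)
    seed: int = 0
    disease: dict = None          # name -> DiseaseTraitParams
    composite: tuple = ("Dig", "Resp", "Other")   # OR'ed into Resist
    ww: WeaningWeightParams | None = None
    nba: LitterSizeParams | None = None
    fixed: FixedEffectConfig = field(default_factory=FixedEffectConfig)

    def __post_init__(self):
        if self.disease is None:
            self.disease = default_disease_params()
        if self.ww is None:
            self.ww = WeaningWeightParams()
        if self.nba is None:
            self.nba = LitterSizeParams()
        for name, v in [("n_sires", self.n_sires), ("n_dams", self.n_dams),
                        ("litters_per_dam", self.litters_per_dam),
                        ("kits_per_litter", self.kits_per_litter),
                        ("n_batches", self.n_batches)]:
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        for name, v in [("fraction_batches_to_ch", self.fraction_batches_to_ch),
                        ("fostering_rate", self.fostering_rate),
                        ("p_ch_male", self.p_ch_male),
                        ("p_ch_female", self.p_ch_female)]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def default_disease_params() -> dict:
    """Disorder blocks matching the observed design: digestive and
    respiratory syndromes plus a latent 'other infectious' disorder whose
    prevalence is solved so the OR composite reaches 26% (S) / 41% (Ch)."""
    return {
        "Dig": DiseaseTraitParams(0.26, 0.42, 0.20, 0.04, 0.48, 0.11, 0.16),
        "Resp": DiseaseTraitParams(0.26, 0.31, 0.19, 0.00, 0.84, 0.14, 0.24),
        "Other": DiseaseTraitParams(0.10, 0.15, 0.10, 0.02, 0.70,
                                    0.0332, 0.0758),
    }


@dataclass
class PhenotypeTable:
    """Per-animal records plus per-litter doe records."""

    animals: pd.DataFrame
    litters: pd.DataFrame


def _invlink(x, link):
    if link == "logit":
        return expit(x)
    if link == "probit":
        return norm.cdf(x)
    raise ValueError(f"unknown link {link!r}")


def expected_prevalence(params: DiseaseTraitParams, environment: str,
                        extra_var: float = 0.0,
                        offsets=((1.0, 0.0),)) -> float:
    """Marginal P(trait = 1) under the liability model.

    Integrates the inverse link over the Gaussian random-effect distribution
    (additive + litter + ``extra_var``, e.g. fixed-effect dispersion) by
    Gauss-Hermite quadrature, averaging over discrete ``(weight, offset)``
    mixture components such as the two sexes.
    """
    var = params.sigma2_a(environment) + params.sigma2_litter(environment) \
        + extra_var
    intercept = solve_intercept(params.prevalence(environment), var,
                                params.link, offsets)
    return marginal_prevalence(intercept, var, params.link, offsets)


def marginal_prevalence(intercept, gauss_var, link="logit",
                        offsets=((1.0, 0.0),)):
    """P(trait = 1) for a given liability intercept and Gaussian variance."""
    sd = math.sqrt(max(gauss_var, 0.0))
    z = _GH_NODES * sd
    total = 0.0
    for w, off in offsets:
        total += w * float(_GH_WEIGHTS @ _invlink(intercept + off + z, link))
    return total


def solve_intercept(target_p, gauss_var, link="logit",
                    offsets=((1.0, 0.0),)) -> float:
    """Liability intercept whose marginal prevalence equals ``target_p``."""
    if not 0.0 < target_p < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    f = lambda mu: marginal_prevalence(mu, gauss_var, link, offsets) - target_p
    return brentq(f, -60.0, 60.0, xtol=1e-12)


def expected_composite_prevalence(disease: dict, components, environment,
                                  shared_var=0.0, sex_offsets=None) -> float:
    """Marginal P(any component disorder) for the OR composite.

    Component liabilities are independent given the shared fixed-effect
    deviation (batch, farm), which is integrated out by quadrature.
    """
    comp = [disease[c] for c in components]
    intercepts = []
    for p in comp:
        var = p.sigma2_a(environment) + p.sigma2_litter(environment) \
            + shared_var
        offs = sex_offsets if sex_offsets else ((1.0, 0.0),)
        intercepts.append(solve_intercept(p.prevalence(environment), var,
                                          p.link, offs))
    shared_sd = math.sqrt(max(shared_var, 0.0))
    total = 0.0
    for w, off in (sex_offsets or ((1.0, 0.0),)):
        s = _GH_NODES * shared_sd
        none_aff = np.ones_like(s)
        for p, mu in zip(comp, intercepts):
            var = p.sigma2_a(environment) + p.sigma2_litter(environment)
            cond = np.array([
                marginal_prevalence(mu + off + si, var, p.link)
                for si in s
            ])
            none_aff = none_aff * (1.0 - cond)
        total += w * float(_GH_WEIGHTS @ (1.0 - none_aff))
    return total


# ---------------------------------------------------------------------------
# population generator


def simulate_population(config: SimulationConfig):
    """Simulate a pedigree, phenotypes and true breeding values.

    Returns ``(Pedigree, PhenotypeTable, true_values)`` where
    ``true_values`` is a DataFrame of the latent additive genetic effects of
    every animal (founders included), one column per genetic trait
    (``<disease>_S``/``_Ch`` liabilities, ``WW_direct``, ``WW_maternal``,
    ``NBA``).
    """
    rng = np.random.default_rng(config.seed)
    fx = config.fixed

    n_s, n_d = config.n_sires, config.n_dams
    # grandparental base generation, so parents form sib families and
    # dam-level genetic variance is separable from permanent environment
    n_bs = config.n_base_sires or max(5, n_s // 3)
    n_bd = config.n_base_dams or max(10, n_d // 3)
    n_base = n_bs + n_bd
    n_parents = n_s + n_d
    n_founders = n_base + n_parents
    sire_ids = np.arange(n_base, n_base + n_s)
    dam_ids = np.arange(n_base + n_s, n_founders)
    par_sire = rng.integers(0, n_bs, size=n_parents)
    par_dam = rng.integers(n_bs, n_base, size=n_parents)

    # --- litters -----------------------------------------------------------
    litters = []
    for parity in range(1, config.litters_per_dam + 1):
        sires_of = rng.integers(0, n_s, size=n_d) + n_base
        batches = rng.integers(0, config.n_batches, size=n_d)
        for j, dam in enumerate(dam_ids):
            litters.append((dam, int(sires_of[j]), parity, int(batches[j])))
    n_lit = len(litters)
    lit_dam = np.array([x[0] for x in litters])
    lit_sire = np.array([x[1] for x in litters])
    lit_parity = np.array([x[2] for x in litters])
    lit_batch = np.array([x[3] for x in litters])

    n_ch_batches = int(round(config.fraction_batches_to_ch * config.n_batches))
    ch_batches = set(
        np.linspace(0, config.n_batches - 1, n_ch_batches * 2 + 1)[1::2]
        .round().astype(int)
    ) if n_ch_batches else set()

    # --- kits --------------------------------------------------------------
    kits_per = config.kits_per_litter
    n_kits = n_lit * kits_per
    kit_litter = np.repeat(np.arange(n_lit), kits_per)
    kit_sire = lit_sire[kit_litter]
    kit_dam = lit_dam[kit_litter]
    kit_batch = lit_batch[kit_litter]
    kit_sex = np.where(rng.random(n_kits) < 0.5, "M", "F").astype(object)

    in_ch_batch = np.isin(kit_batch, list(ch_batches))
    p_go = np.where(kit_sex == "M", config.p_ch_male, config.p_ch_female)
    kit_env = np.where(in_ch_batch & (rng.random(n_kits) < p_go), "Ch", "S")
    kit_env = kit_env.astype(object)
    kit_farm = np.where(
        kit_env == "Ch", rng.integers(1, config.n_ch_farms + 1, n_kits), 0
    )

    # --- pedigree object ---------------------------------------------------
    n_total = n_founders + n_kits
    ids = np.array(
        [f"BS{i+1}" for i in range(n_bs)]
        + [f"BD{i+1}" for i in range(n_bd)]
        + [f"S{i+1}" for i in range(n_s)]
        + [f"D{i+1}" for i in range(n_d)]
        + [f"K{i+1}" for i in range(n_kits)],
        dtype=object,
    )
    sire_idx = np.concatenate([np.full(n_base, -1), par_sire, kit_sire])
    dam_idx = np.concatenate([np.full(n_base, -1), par_dam, kit_dam])
    sex = np.concatenate(
        [np.array(["M"] * n_bs + ["F"] * n_bd
                  + ["M"] * n_s + ["F"] * n_d, dtype=object), kit_sex]
    )
    batch = np.concatenate([np.full(n_founders, -1), kit_batch])
    env = np.concatenate(
        [np.array(["S"] * n_founders, dtype=object), kit_env]
    )
    # litter labels: litter ordinal
    litter_idx = np.concatenate([np.full(n_founders, -1), kit_litter])
    ped = Pedigree(ids=ids, sire=sire_idx, dam=dam_idx, sex=sex,
                   batch=batch, environment=env, litter=litter_idx)

    # --- fostering ---------------------------------------------------------
    fostered = np.nonzero(rng.random(n_kits) < config.fostering_rate)[0]
    events = []
    for k in fostered:
        # adoptive dam: dam of another litter in the same batch
        cands = np.nonzero((lit_batch == kit_batch[k])
                           & (np.arange(n_lit) != kit_litter[k]))[0]
        if len(cands) == 0:
            continue
        target_lit = int(rng.choice(cands))
        events.append((ids[n_founders + k], ids[lit_dam[target_lit]],
                       target_lit))
    ped = assign_rearing_effects(ped, [(a, b) for a, b, _ in events])
    # rearing litter must be the adoptive litter (a dam can have several)
    for a, _, tl in events:
        ped.litter[ped.index_of(a)] = tl
    rear_litter = ped.litter[n_founders:]
    rear_dam = ped.rearing_dam[n_founders:]

    # --- genetic effects ---------------------------------------------------
    trait_names, G = _genetic_covariance(config)
    chol = np.linalg.cholesky(G)
    n_tr = len(trait_names)
    bv = np.empty((n_total, n_tr))
    bv[:n_base] = rng.standard_normal((n_base, n_tr)) @ chol.T
    mend_p = rng.standard_normal((n_parents, n_tr)) @ (chol.T * math.sqrt(0.5))
    bv[n_base:n_founders] = 0.5 * (bv[par_sire] + bv[par_dam]) + mend_p
    mend = rng.standard_normal((n_kits, n_tr)) @ (chol.T * math.sqrt(0.5))
    bv[n_founders:] = 0.5 * (bv[kit_sire] + bv[kit_dam]) + mend

    col = {t: i for i, t in enumerate(trait_names)}

    # --- fixed-effect level values ----------------------------------------
    batch_eff_d = rng.normal(0, fx.batch_sd, config.n_batches)
    farm_eff = rng.normal(0, fx.farm_sd, config.n_ch_farms + 1)
    farm_eff[0] = 0.0
    batch_eff_ww = rng.normal(0, fx.batch_sd_ww, config.n_batches)
    parity_eff_ww = rng.normal(0, fx.parity_sd_ww, config.litters_per_dam)
    ys_eff = rng.normal(0, fx.year_season_sd_nba, 15)
    ps_eff = rng.normal(0, fx.parity_status_sd_nba, 9)
    sex_off_d = np.where(kit_sex == "M", fx.sex_effect_disease / 2,
                         -fx.sex_effect_disease / 2)
    shared_fixed_var = {
        "S": fx.batch_sd**2,
        "Ch": fx.batch_sd**2 + fx.farm_sd**2,
    }
    sex_offsets = ((0.5, fx.sex_effect_disease / 2),
                   (0.5, -fx.sex_effect_disease / 2))

    # --- disease phenotypes ------------------------------------------------
    animals = pd.DataFrame({
        "animal_id": ids[n_founders:],
        "sire_id": ids[kit_sire],
        "dam_id": ids[kit_dam],
        "rearing_dam_id": ids[rear_dam],
        "litter": rear_litter,
        "batch": kit_batch,
        "sex": kit_sex,
        "environment": kit_env,
        "farm": kit_farm,
    })

    disease_outcomes = {}
    for name, p in config.disease.items():
        y = np.zeros(n_kits, dtype=int)
        for e in ("S", "Ch"):
            mask = kit_env == e
            if not mask.any():
                continue
            var = p.sigma2_a(e) + p.sigma2_litter(e) + shared_fixed_var[e]
            mu = solve_intercept(p.prevalence(e), var, p.link, sex_offsets)
            c_lit = rng.normal(0, math.sqrt(p.sigma2_litter(e)), n_lit)
            a = bv[n_founders:, col[f"{name}_{e}"]]
            liab = (mu + batch_eff_d[kit_batch] + farm_eff[kit_farm]
                    + sex_off_d + a + c_lit[rear_litter])
            resid = (rng.logistic(0, 1, n_kits) if p.link == "logit"
                     else rng.standard_normal(n_kits))
            y = np.where(mask, (liab + resid > 0).astype(int), y)
        disease_outcomes[name] = y
        animals[name] = y

    if config.composite:
        present = [c for c in config.composite if c in disease_outcomes]
        if present:
            animals["Resist"] = np.clip(
                sum(disease_outcomes[c] for c in present), 0, 1
            )

    # --- weaning weight ----------------------------------------------------
    if config.ww is not None:
        w = config.ww
        c_lit = rng.normal(0, math.sqrt(w.sigma2_litter), n_lit)
        me = rng.normal(0, math.sqrt(w.sigma2_mat_env), n_total)
        ww = (w.mean + batch_eff_ww[kit_batch]
              + np.where(kit_sex == "M", fx.sex_effect_ww / 2,
                         -fx.sex_effect_ww / 2)
              + parity_eff_ww[lit_parity[kit_litter] - 1]
              + bv[n_founders:, col["WW_direct"]]
              + bv[rear_dam, col["WW_maternal"]]
              + c_lit[rear_litter] + me[rear_dam]
              + rng.normal(0, math.sqrt(w.sigma2_e), n_kits))
        recorded = rng.random(n_kits) < config.fraction_ww_recorded
        animals["WW"] = np.where(recorded, np.round(ww, 1), np.nan)

    # --- litter size -------------------------------------------------------
    litters_df = pd.DataFrame({
        "litter": np.arange(n_lit),
        "dam_id": ids[lit_dam],
        "sire_id": ids[lit_sire],
        "parity": lit_parity,
        "batch": lit_batch,
    })
    if config.nba is not None:
        nb = config.nba
        pe = rng.normal(0, math.sqrt(nb.sigma2_perm_env), n_total)
        ys = rng.integers(0, len(ys_eff), n_lit)
        ps = np.minimum(lit_parity - 1, len(ps_eff) - 1) \
            + rng.integers(0, 2, n_lit)
        ps = np.minimum(ps, len(ps_eff) - 1)
        nba = (nb.mean + ys_eff[ys] + ps_eff[ps]
               + bv[lit_dam, col["NBA"]] + pe[lit_dam]
               + rng.normal(0, math.sqrt(nb.sigma2_e), n_lit))
        litters_df["year_season"] = ys
        litters_df["parity_status"] = ps
        litters_df["NBA"] = np.maximum(np.round(nba), 0).astype(int)

    true_values = pd.DataFrame(bv, columns=trait_names)
    true_values.insert(0, "animal_id", ids)
    return ped, PhenotypeTable(animals=animals, litters=litters_df), true_values


def _genetic_covariance(config: SimulationConfig):
    """Joint additive covariance over all latent traits.

    Disease blocks carry the cross-environment correlation; the weaning
    weight block carries the direct-maternal covariance; blocks are mutually
    independent by default (cross-block correlations of the composite trait
    with production emerge only through sampling, not by construction).
    """
    names, blocks = [], []
    for name, p in config.disease.items():
        sa_s, sa_c = p.sigma2_a_S, p.sigma2_a_Ch
        cov = p.r_g_env * math.sqrt(sa_s * sa_c)
        blocks.append(np.array([[sa_s, cov], [cov, sa_c]]))
        names += [f"{name}_S", f"{name}_Ch"]
    if config.ww is not None:
        w = config.ww
        blocks.append(np.array([[w.sigma2_a, w.cov_a_m],
                                [w.cov_a_m, w.sigma2_m]]))
        names += ["WW_direct", "WW_maternal"]
    if config.nba is not None:
        blocks.append(np.array([[config.nba.sigma2_a]]))
        names += ["NBA"]
    n = sum(b.shape[0] for b in blocks)
    G = np.zeros((n, n))
    i = 0
    for b in blocks:
        k = b.shape[0]
        G[i:i + k, i:i + k] = b
        i += k
    ev = np.linalg.eigvalsh(G)
    if ev.min() < -1e-8:
        raise ValueError(
            "implied genetic covariance matrix is not positive semi-definite"
        )
    G[np.diag_indices_from(G)] += max(0.0, -ev.min()) + 1e-12
    return names, G


def write_population(ped: Pedigree, pheno: PhenotypeTable,
                     true_values: pd.DataFrame, out_dir):
    """Write pedigree/phenotype/true-value tables as CSV files."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped.to_frame().to_csv(out / "pedigree.csv", index=False)
    pheno.animals.to_csv(out / "animals.csv", index=False)
    pheno.litters.to_csv(out / "litters.csv", index=False)
    true_values.to_csv(out / "true_values.csv", index=False,
                       float_format="%.6f")
    return out
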