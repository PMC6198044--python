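"""Reference parameter sets for a French maternal rabbit line selected for
litter size and weaning weight, with disease-resistance traits recorded in
a selection (S) and a challenging (Ch) environment.

These are the package defaults for breeding-objective and selection-response
calculations: genetic variances and correlations among litter size (NBA),
the direct and maternal components of weaning weight (WW, in g) and the
composite disease trait Resist expressed in each environment (in %,
observed scale).

The liability-scale components of Resist are converted to the observed
percentage scale with the threshold-model transfer factor z^2 / (p (1 - p))
(z the standard-normal density at the prevalence threshold), and the
observed-scale phenotypic variance of a binary trait scored in % is
p (1 - p) * 100^2.  The direct-maternal genetic covariance of weaning
weight is negative (r = -0.71); with it, the weaning-weight phenotypic
variance decomposes exactly into the printed components.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

from .objectives import BreedingObjective
from .response import (RecordType, RecordingPlan, ResponseParameters,
                       SchemeConfig)

TRAITS = ["NBA", "WW_direct", "WW_maternal", "Resist_S", "Resist_Ch"]

#: prevalence of the composite disorder per environment
PREVALENCE = {"S": 0.26, "Ch": 0.41}

#: liability-scale (logit) variance components of Resist
RESIST_LIABILITY = {
    "S": dict(sigma2_a=0.15, sigma2_litter=0.14),
    "Ch": dict(sigma2_a=0.29, sigma2_litter=0.01),
}

#: litter size (kits) and weaning weight (g) variance components
NBA_COMPONENTS = dict(sigma2_a=1.71, sigma2_perm_env=0.32, sigma2_e=8.47,
                      sigma2_p=10.49)
WW_COMPONENTS = dict(sigma2_a=2986.0, sigma2_litter=1218.0,
                     sigma2_mat_env=730.0, sigma2_m=474.0, cov_a_m=-842.0,
                     sigma2_e=5620.0, sigma2_p=10186.0)

LOGIT_RESIDUAL = math.pi**2 / 3.0

#: genetic correlations among the five breeding-value entities
GENETIC_CORRELATIONS = {
    ("NBA", "WW_direct"): -0.22,
    ("NBA", "WW_maternal"): 0.51,
    ("NBA", "Resist_S"): -0.08,
    ("NBA", "Resist_Ch"): -0.06,
    ("WW_direct", "WW_maternal"): -0.71,
    ("WW_direct", "Resist_S"): -0.34,
    ("WW_direct", "Resist_Ch"): -0.05,
    ("WW_maternal", "Resist_S"): -0.06,
    ("WW_maternal", "Resist_Ch"): -0.04,
    ("Resist_S", "Resist_Ch"): 0.70,
}

#: phenotypic correlations of records on the same animal (WW vs Resist)
PHENOTYPIC_CORRELATIONS = {
    ("WW", "Resist_S"): -0.13,
    ("WW", "Resist_Ch"): -0.11,
}


def dempster_lerner_factor(p):
    """Liability-to-observed transfer factor z^2 / (p (1 - p)) for a binary
    trait with prevalence p (normal-threshold approximation)."""
    z = norm.pdf(norm.ppf(1.0 - p))
    return z * z / (p * (1.0 - p))


def resist_observed_components(env):
    """Observed-scale (%) variance components of the composite disorder.

    Heritability and common-litter ratios transfer from the liability scale
    with the threshold factor; the phenotypic variance is the binomial
    p(1-p) scaled to percent squared.
    """
    p = PREVALENCE[env]
    lia = RESIST_LIABILITY[env]
    s2p_lia = lia["sigma2_a"] + lia["sigma2_litter"] + LOGIT_RESIDUAL
    f = dempster_lerner_factor(p)
    s2p_obs = p * (1 - p) * 100.0**2
    s2a = lia["sigma2_a"] / s2p_lia * f * s2p_obs
    s2l = lia["sigma2_litter"] / s2p_lia * f * s2p_obs
    return dict(sigma2_a=s2a, sigma2_litter=s2l,
                sigma2_e=s2p_obs - s2a - s2l, sigma2_p=s2p_obs)


def genetic_covariance_matrix() -> np.ndarray:
    """5x5 genetic covariance over NBA, WW_direct, WW_maternal, Resist_S,
    Resist_Ch (trait units: kits, g, g, %, %)."""
    var = [
        NBA_COMPONENTS["sigma2_a"],
        WW_COMPONENTS["sigma2_a"],
        WW_COMPONENTS["sigma2_m"],
        resist_observed_components("S")["sigma2_a"],
        resist_observed_components("Ch")["sigma2_a"],
    ]
    sd = np.sqrt(var)
    G = np.diag(np.array(var, float))
    for (a, b), r in GENETIC_CORRELATIONS.items():
        i, j = TRAITS.index(a), TRAITS.index(b)
        G[i, j] = G[j, i] = r * sd[i] * sd[j]
    return G


def response_parameters() -> ResponseParameters:
    """Record decompositions and genetic covariances for the deterministic
    selection-response predictor."""
    G = genetic_covariance_matrix()
    ww = WW_COMPONENTS
    nba = NBA_COMPONENTS
    rs = resist_observed_components("S")
    rch = resist_observed_components("Ch")
    records = {
        "WW": RecordType("WW", "WW_direct", "WW_maternal",
                         var_litter=ww["sigma2_litter"],
                         var_mat_env=ww["sigma2_mat_env"],
                         var_resid=ww["sigma2_e"]),
        "Resist_S": RecordType("Resist_S", "Resist_S",
                               var_litter=rs["sigma2_litter"],
                               var_resid=rs["sigma2_e"]),
        "Resist_Ch": RecordType("Resist_Ch", "Resist_Ch",
                                var_litter=rch["sigma2_litter"],
                                var_resid=rch["sigma2_e"]),
        "NBA": RecordType("NBA", "NBA", var_perm_env=nba["sigma2_perm_env"],
                          var_resid=nba["sigma2_e"]),
    }
    params = ResponseParameters(traits=list(TRAITS), G=G, records=records)
    # same-animal residual covariances reproduce the phenotypic correlations
    for (r1, r2), rp in PHENOTYPIC_CORRELATIONS.items():
        s2p1 = ww["sigma2_p"] if r1 == "WW" else None
        s2p2 = rs["sigma2_p"] if r2 == "Resist_S" else rch["sigma2_p"]
        target = rp * math.sqrt(s2p1 * s2p2)
        a, b = records[r1], records[r2]
        gen = (params.gcov(G, a.direct, b.direct)
               + 0.5 * params.gcov(G, a.maternal, b.direct))
        params.resid_cov[frozenset((r1, r2))] = target - gen
    return params


# ---------------------------------------------------------------------------
# breeding objectives and schemes


def standard_objectives() -> dict:
    """The four comparison objectives: production only, disease resistance
    in either environment, or in both (weights in EUR per trait unit)."""
    base = {"NBA": 3.0, "WW_direct": 0.15, "WW_maternal": 0.15}
    return {
        "HResist_S_Ch": BreedingObjective(
            "HResist_S_Ch", {**base, "Resist_S": -65.0, "Resist_Ch": -65.0}),
        "HResist_S": BreedingObjective(
            "HResist_S", {**base, "Resist_S": -130.0}),
        "HResist_Ch": BreedingObjective(
            "HResist_Ch", {**base, "Resist_Ch": -130.0}),
        "HProduction": BreedingObjective("HProduction", dict(base)),
    }


def nucleus_scheme(objective_name="HProduction",
                   ch_records=False) -> SchemeConfig:
    """35-sire / 140-dam nucleus, 7 kits per litter, 15% / 25% selected.

    Recording follows the objective: production-only schemes record no
    disease trait; disease schemes record Resist on the candidate and all
    sibs in S, or move a quarter of the sibs' records to Ch when
    ``ch_records`` is set.  Candidates carry no litter-size record at
    selection age; dam records can be enabled via the returned config.
    """
    if objective_name == "HProduction":
        rp = RecordingPlan(own=("WW",), sib_recorded=("WW",),
                           fraction_sibs_ch=0.0, dam_records=0)
    else:
        rp = RecordingPlan(
            own=("WW", "Resist_S"),
            sib_recorded=("WW", "Resist_S"),
            fraction_sibs_ch=0.25 if ch_records else 0.0,
            ch_trait="Resist_Ch" if ch_records else None,
            s_trait="Resist_S",
            dam_records=0,
        )
    return SchemeConfig(recording=rp)
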