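"""Derived genetic parameters: heritabilities and variance ratios on the
declared phenotypic-variance convention, sampling-based standard errors,
boundary likelihood-ratio tests, and between-environment comparisons.

Scale convention for threshold (logit) traits: the working-scale residual is
fixed at 1.0 and the liability-scale phenotypic variance is reconstructed as
``sigma2_a + sigma2_litter + pi^2/3`` (logistic residual variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_model import FitResult

LOGIT_RESIDUAL = math.pi**2 / 3.0


def liability_phenotypic_variance(sigma2_a, sigma2_litter) -> float:
    """sigma2_p on the logistic liability scale."""
    return sigma2_a + sigma2_litter + LOGIT_RESIDUAL


def variance_ratio(numerator, sigma2_p) -> float:
    """Ratio of one or several variance components to phenotypic variance.

    ``numerator`` may be a scalar or an iterable of components (e.g. additive
    plus permanent environment for repeatability).
    """
    if sigma2_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    num = float(np.sum(numerator))
    return num / sigma2_p


def sample_parameter_se(fit: FitResult, expression, n_draws=10_000, seed=0):
    """Sampling-based standard error of a parameter function.

    Draws variance-component vectors from a multivariate Gaussian centred at
    the REML estimates with the average-information sampling covariance,
    rejecting draws with negative variances, and evaluates ``expression``
    (a callable mapping the parameter vector to the scalar of interest) on
    each draw.  Returns ``(se, normality_ok, draws)``; normality of the draw
    distribution is assessed with the D'Agostino-Pearson omnibus test at 5%
    (reported, never used to gate anything).
    """
    theta, cov, labels, is_var = _free_parameters(fit)
    cov = _nearest_psd(cov)
    if not cov.any():
        return 0.0, True, np.full(n_draws,
                                  expression(dict(zip(labels, theta))))
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    chol = np.linalg.cholesky(cov + np.eye(len(theta)) * 1e-12 *
                              max(cov.diagonal().max(), 1.0))
    got = 0
    batch = max(n_draws, 1000)
    while got < n_draws:
        cand = theta + rng.standard_normal((batch, len(theta))) @ chol.T
        ok = np.all(cand[:, is_var] >= 0.0, axis=1)
        take = cand[ok][: n_draws - got]
        for row in take:
            draws[got] = expression(dict(zip(labels, row)))
            got += 1
    se = float(np.std(draws, ddof=1))
    if se == 0.0 or np.ptp(draws) == 0.0:
        return se, True, draws
    _, p_norm = stats.normaltest(draws)
    return se, bool(p_norm > 0.05), draws


def _free_parameters(fit: FitResult):
    vc = fit.varcomp
    labels = list(vc.free_labels)
    theta = []
    for kind in labels:
        theta.append(_lookup_label(vc, kind))
    cov = vc.sampling_cov
    if cov is None:
        cov = np.zeros((len(theta), len(theta)))
    is_var = np.array(["," not in lab for lab in labels])
    return np.asarray(theta, float), np.asarray(cov, float), labels, is_var


def _lookup_label(vc, label):
    name, inside = label.split("[")
    inside = inside.rstrip("]")
    parts = inside.split(",")
    if name == "residual":
        idx = [vc.trait_names.index(p) for p in parts]
        i = idx[0]
        j = idx[-1]
        return float(vc.residual[i, j])
    labels, mat = vc.terms[name]
    chs = [lab.split("@")[0] for lab in labels]
    i = chs.index(parts[0])
    j = chs.index(parts[-1]) if len(parts) > 1 else i
    if len(parts) > 1 and parts[0] == parts[-1]:
        # same trait twice: off-diagonal of a 2-channel same-trait term
        j = i + 1
    return float(mat[i, j])


def _nearest_psd(m):
    m = 0.5 * (m + m.T)
    ev, vec = np.linalg.eigh(m)
    if ev.min() >= 0:
        return m
    ev = np.clip(ev, 0.0, None)
    return vec @ np.diag(ev) @ vec.T


def delta_method_se(theta, cov, expression, labels, h=1e-6):
    """First-order (delta-method) SE of ``expression`` for cross-checks."""
    theta = np.asarray(theta, float)
    grad = np.empty(len(theta))
    f0 = expression(dict(zip(labels, theta)))
    for i in range(len(theta)):
        tp = theta.copy()
        step = h * max(abs(theta[i]), 1e-3)
        tp[i] += step
        grad[i] = (expression(dict(zip(labels, tp))) - f0) / step
    return float(np.sqrt(grad @ cov @ grad))


def compare_h2(h2_a, se_a, h2_b, se_b, df=None):
    """Two-sided Student's t comparison of two heritabilities.

    ``df`` defaults to a Welch-Satterthwaite combination treating each SE
    as based on a large number of sampling draws (effectively normal).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    t = (h2_a - h2_b) / math.sqrt(se_a**2 + se_b**2)
    if df is None:
        df = 10_000
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, min(p, 1.0)


def mixture_lrt_pvalue(T, q) -> float:
    """Boundary LRT p-value from the 50:50 chi-square mixture.

    For a test of one variance component (or of a correlation fixed at 1)
    the null distribution is an equal mixture of chi2 with ``q`` and
    ``q + 1`` degrees of freedom, where ``q`` counts the random effects of
    the reduced model (residual excluded) and chi2_0 is a point mass at 0.
    """
    if T < 0:
        raise ValueError("likelihood-ratio statistic must be non-negative")
    if q < 0:
        raise ValueError("q must be a non-negative count")
    # chi2_0 is a point mass at 0: P(chi2_0 > T) = 0 for every T >= 0
    p_q = 0.0 if q == 0 else float(stats.chi2.sf(T, q))
    p_q1 = float(stats.chi2.sf(T, q + 1))
    return 0.5 * p_q + 0.5 * p_q1


def lrt_statistic(full: FitResult, reduced: FitResult) -> float:
    """-2 (logL_reduced - logL_full), floored at 0."""
    return max(0.0, 2.0 * (full.loglik - reduced.loglik))


@dataclass
class ParameterReport:
    ratios: pd.DataFrame         # per trait: h2, c2..., sigma2_p, SEs
    correlations: pd.DataFrame   # genetic above diagonal, phenotypic below

    def to_csv(self, path_ratios, path_corr):
        self.ratios.to_csv(path_ratios)
        self.correlations.to_csv(path_corr)


def heritability(fit: FitResult, trait=None, threshold=None, term="additive",
                 litter_term="litter", n_draws=2000, seed=0):
    """h2 with its sampling SE for a single-trait fit.

    ``threshold`` defaults to the fit's link; for threshold fits the
    denominator uses the logistic-residual convention.
    """
    vc = fit.varcomp
    trait = trait or vc.trait_names[0]
    if threshold is None:
        threshold = fit.spec.link == "logit-threshold"
    chs, mat = vc.terms[term]
    i = [c.split("@")[0] for c in chs].index(trait)
    s2a_label = f"{term}[{trait}]"

    def expr(p):
        s2a = p.get(s2a_label, mat[i, i])
        s2l = p.get(f"{litter_term}[{trait}]", 0.0)
        if threshold:
            s2p = liability_phenotypic_variance(s2a, s2l)
        else:
            s2p = s2a + sum(v for k, v in p.items()
                            if "," not in k and k != s2a_label)
        return s2a / s2p

    theta, cov, labels, _ = _free_parameters(fit)
    h2 = expr(dict(zip(labels, theta)))
    se, norm_ok, _ = sample_parameter_se(fit, expr, n_draws=n_draws,
                                         seed=seed)
    return h2, se, norm_ok


def assemble_report(fits: dict, n_draws=2000, seed=0) -> ParameterReport:
    """Collect single-trait fits into a parameter table.

    ``fits`` maps trait name to FitResult.  Genetic correlations from
    bivariate fits can be appended by the caller; a single-trait collection
    yields an identity correlation matrix.
    """
    rows = {}
    names = list(fits)
    for name, fit in fits.items():
        vc = fit.varcomp
        threshold = fit.spec.link == "logit-threshold"
        comp = {}
        for term, (chs, mat) in vc.terms.items():
            for k, ch in enumerate(chs):
                if ch.split("@")[0] == name or len(fits) == 1:
                    comp[term] = float(mat[k, k])
                    break
        s2e = LOGIT_RESIDUAL if threshold else float(vc.residual[0, 0])
        s2p = sum(comp.values()) + s2e
        h2, se, _ = heritability(fit, n_draws=n_draws, seed=seed)
        row = {"sigma2_p": s2p, "h2": h2, "h2_se": se}
        for term, v in comp.items():
            if term != "additive":
                row[f"c2_{term}"] = v / s2p
        rows[name] = row
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    return ParameterReport(ratios=pd.DataFrame(rows).T, correlations=corr)
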