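"""Breeding-objective algebra.

An objective is a linear combination H = w' A of true breeding values with
weights in currency per trait unit.  Covariances and correlations between
objectives follow from the genetic covariance matrix of the component
traits: Cov(H_i, H_j) = w_i' G w_j.  The desired-gains search adjusts
weights until the predicted responses of selected traits match stated
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BreedingObjective:
    name: str
    weights: dict                 # trait -> currency per trait unit

    def vector(self, traits):
        return np.array([float(self.weights.get(t, 0.0)) for t in traits])

    def get(self, t, default=0.0):
        return self.weights.get(t, default)


def _as_vectors(wi, wj, traits, G):
    G = np.asarray(G, float)
    for obj in (wi, wj):
        for t in obj.weights:
            if t not in traits:
                raise ValueError(f"trait {t!r} absent from covariance matrix")
    return wi.vector(traits), wj.vector(traits), G


def objective_covariance(wi: BreedingObjective, wj: BreedingObjective,
                         traits, G) -> float:
    """w_i' G w_j (currency squared); missing traits carry weight 0."""
    vi, vj, G = _as_vectors(wi, wj, traits, G)
    return float(vi @ G @ vj)


def objective_correlation(wi: BreedingObjective, wj: BreedingObjective,
                          traits, G) -> float:
    cov = objective_covariance(wi, wj, traits, G)
    vi_var = objective_covariance(wi, wi, traits, G)
    vj_var = objective_covariance(wj, wj, traits, G)
    if vi_var <= 0 or vj_var <= 0:
        raise ValueError("objective with zero variance")
    r = cov / np.sqrt(vi_var * vj_var)
    return float(np.clip(r, -1.0, 1.0))


def objective_correlation_table(objectives: dict, traits, G):
    import pandas as pd

    names = list(objectives)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                r = objective_correlation(objectives[a], objectives[b],
                                          traits, G)
                out.iloc[i, j] = out.iloc[j, i] = r
    return out


def desired_gains_search(base: BreedingObjective, targets: dict, predictor,
                         tol=0.02, max_iter=60, damping=0.6,
                         step_frac=0.15) -> BreedingObjective:
    """Adjust index weights until predicted gains match desired gains.

    Selection responses are invariant to a common rescaling of the weights,
    so only the *direction* of the response vector over the targeted traits
    is matched (the classical desired-gains convention): both the predicted
    and the target response vectors are normalized to unit length before
    comparison, and the returned weights keep the base objective's overall
    scale.  ``predictor`` maps a BreedingObjective to a dict of per-trait
    responses (e.g. a closure over
    :func:`cuniqg.response.predict_response`).  Damped Gauss-Newton with a
    ridge guard; best-effort weights are returned with a warning when a
    target direction is unreachable or insensitive to every weight.
    """
    import warnings

    trait_list = list(targets)
    w = {t: float(v) for t, v in base.weights.items()}
    for t in trait_list:
        w.setdefault(t, 0.0)
    wscale = np.linalg.norm(list(w.values())) or 1.0

    def renorm(wd):
        nrm = np.linalg.norm(list(wd.values()))
        if nrm <= 0:
            return wd
        return {k: v * wscale / nrm for k, v in wd.items()}

    def resp_dir(wd):
        r = predictor(BreedingObjective(base.name, wd))
        vec = np.array([r[t] for t in trait_list])
        nrm = np.linalg.norm(vec)
        return vec / nrm if nrm > 0 else vec

    tgt = np.array([float(targets[t]) for t in trait_list])
    tnrm = np.linalg.norm(tgt)
    if tnrm == 0:
        return BreedingObjective(base.name, w)
    tgt = tgt / tnrm

    best_w, best_err = dict(w), np.inf
    for _ in range(max_iter):
        r = resp_dir(w)
        err = float(np.max(np.abs(r - tgt)))
        if err < best_err:
            best_err, best_w = err, dict(w)
        if err < tol:
            return BreedingObjective(base.name, w)
        J = np.zeros((len(trait_list), len(trait_list)))
        for j, t in enumerate(trait_list):
            h = step_frac * max(abs(w[t]), 0.1 * wscale)
            wp = dict(w)
            wp[t] += h
            J[:, j] = (resp_dir(wp) - r) / h
        if np.abs(J).max() < 1e-12:
            warnings.warn("responses insensitive to weights; best effort")
            break
        ridge = 1e-6 * np.trace(J.T @ J) / len(trait_list)
        try:
            delta = np.linalg.solve(J.T @ J + ridge * np.eye(len(J)),
                                    J.T @ (tgt - r))
        except np.linalg.LinAlgError:
            break
        if not np.isfinite(delta).all():
            break
        step = damping
        for t, dlt in zip(trait_list, delta):
            # trust region: cap each move at one base-scale unit
            move = np.clip(step * dlt, -wscale, wscale)
            w[t] += move
        w = renorm(w)
    if best_err >= tol:
        warnings.warn(
            f"desired-gains search stopped at direction error "
            f"{best_err:.3f}"
        )
    return BreedingObjective(base.name, best_w)
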