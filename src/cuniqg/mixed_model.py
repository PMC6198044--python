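"""Henderson mixed-model equations and REML for pedigreed animal models.

Supports multi-trait linear animal models with arbitrary random terms
(additive genetic with pedigree covariance, maternal genetic on the rearing
dam, common-litter, maternal environmental, permanent environmental) and
single-trait threshold (logit-link) models for binary disorders fitted by
penalized quasi-likelihood.

Random terms are declared as sets of *channels*: a channel is one column
group of effects (a trait routed through an incidence rule), and a term
carries a free covariance matrix across its channels sharing one covariance
structure (pedigree A or identity).  The direct-maternal genetic covariance
of weaning weight is therefore just a 2-channel genetic term (direct on the
animal, maternal on the rearing dam).

Estimation maximizes the exact restricted log-likelihood, evaluated through
a sparse factorization of the mixed-model equations; updates are Newton
steps using the average-information matrix (computed exactly from MME
solves) with numerically evaluated scores, safeguarded by step halving and
variance floors at the parameter-space boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy import stats

from .pedigree import Pedigree, compute_A_inverse, log_det_A

VAR_FLOOR = 1e-8


class ModelError(ValueError):
    pass


@dataclass
class Channel:
    """One effect column-group of a random term."""

    trait: str          # TraitSpec.name this channel loads on
    incidence: str      # column of the trait's table giving the level id


@dataclass
class RandomTerm:
    name: str
    structure: str                  # 'pedigree' | 'iid'
    channels: list
    start: np.ndarray | None = None     # initial covariance across channels
    fixed: np.ndarray | None = None     # boolean mask of frozen entries

    @property
    def n_channels(self):
        return len(self.channels)


@dataclass
class TraitSpec:
    name: str
    response: str
    table: str = "animals"          # 'animals' | 'litters'
    fixed: list = field(default_factory=list)
    subset: str | None = None       # pandas query string
    unit: str | None = None         # residual grouping column


@dataclass
class ModelSpec:
    traits: list
    random: list
    link: str = "identity"          # 'identity' | 'logit-threshold'

    def __post_init__(self):
        binary_ok = self.link == "identity" or len(self.traits) == 1
        if not binary_ok:
            raise ModelError("threshold link supports single-trait models")


@dataclass
class DesignBundle:
    y: np.ndarray
    trait_of_obs: np.ndarray
    X: sp.csr_matrix
    fixed_cols: dict            # factor -> column slice in X
    terms: list                 # RandomTerm
    Zc: list                    # per term: list of per-channel csr (n_obs x q)
    n_levels: list              # per term
    Kinv: list                  # per term: sparse K^-1 or None (iid)
    K_solve: list               # per term: callable v -> K v
    logdetK: list               # per term: log|K|
    resid_pairs: dict           # (t,u) -> (obs_idx_t, obs_idx_u) co-observed
    resid_free: np.ndarray      # bool matrix: residual entries estimable
    resid_groups: list          # multi-obs units: arrays of obs indices
    n_traits: int
    trait_names: list
    spec: ModelSpec
    obs_table_row: np.ndarray   # row index into source table per observation
    x_rank: int
    W: sp.csr_matrix = None     # [X | Z...] incidence, theta-independent


@dataclass
class VarianceComponents:
    """Covariance matrices per random term plus residual, with the AI-based
    sampling covariance of the free parameters."""

    terms: dict                  # name -> (labels, matrix)
    residual: np.ndarray
    trait_names: list
    sampling_cov: np.ndarray | None = None
    free_labels: list | None = None

    def variance(self, term, channel=0, channel2=None):
        labels, mat = self.terms[term]
        j = channel if channel2 is None else channel2
        return float(mat[channel, j])


@dataclass
class FitResult:
    spec: ModelSpec
    varcomp: VarianceComponents
    loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_cols: dict
    u: dict
    converged: bool
    boundary: bool
    n_iter: int
    trace: list
    design: DesignBundle = None
    n_obs: int = 0


# ---------------------------------------------------------------------------
# design assembly


def _dummy(col: pd.Series):
    levels = pd.unique(col)
    if len(levels) < 2:
        return np.zeros((len(col), 0)), levels
    codes = pd.Categorical(col, categories=levels).codes
    out = np.zeros((len(col), len(levels) - 1))
    for j in range(1, len(levels)):
        out[codes == j, j - 1] = 1.0
    return out, levels


def build_design(spec: ModelSpec, ped: Pedigree, pheno) -> DesignBundle:
    """Assemble response, fixed and random incidence matrices.

    Maternal and common-litter channels must be routed through the rearing
    dam / rearing litter columns, so cross-fostered kits point to the
    adoptive dam while the additive channel follows the biological pedigree.
    """
    tables = {"animals": pheno.animals, "litters": pheno.litters}
    y_parts, trait_parts, rows_parts = [], [], []
    X_blocks, fixed_cols = [], {}
    col_off = 0
    unit_keys = []
    for t_i, ts in enumerate(spec.traits):
        df = tables[ts.table]
        if ts.subset:
            df = df.query(ts.subset)
        if ts.response not in df.columns:
            raise ModelError(f"response {ts.response!r} not in {ts.table}")
        resp = pd.to_numeric(df[ts.response], errors="coerce")
        keep = resp.notna()
        df = df[keep]
        resp = resp[keep]
        y_parts.append(resp.to_numpy(float))
        trait_parts.append(np.full(len(df), t_i))
        rows_parts.append(df.index.to_numpy())
        blocks = [np.ones((len(df), 1))]
        fixed_cols[(ts.name, "intercept")] = (col_off, col_off + 1)
        col_off += 1
        for fac in ts.fixed:
            if fac not in df.columns:
                raise ModelError(
                    f"fixed factor {fac!r} absent from {ts.table} table"
                )
            dm, _ = _dummy(df[fac].astype(str))
            fixed_cols[(ts.name, fac)] = (col_off, col_off + dm.shape[1])
            col_off += dm.shape[1]
            blocks.append(dm)
        X_blocks.append(np.hstack(blocks))
        unit_col = ts.unit or ("animal_id" if ts.table == "animals"
                               else "litter")
        unit_keys.append(df[unit_col].astype(str).to_numpy())

    y = np.concatenate(y_parts)
    trait_of_obs = np.concatenate(trait_parts)
    obs_rows = np.concatenate(rows_parts)
    n_obs = len(y)
    X = np.zeros((n_obs, col_off))
    pos = 0
    cstart = 0
    for blk in X_blocks:
        X[pos:pos + blk.shape[0], cstart:cstart + blk.shape[1]] = blk
        pos += blk.shape[0]
        cstart += blk.shape[1]
    x_rank = np.linalg.matrix_rank(X)
    if x_rank < X.shape[1]:
        raise ModelError(
            "fixed-effect design is rank deficient (confounded factors)"
        )

    trait_index = {ts.name: i for i, ts in enumerate(spec.traits)}
    trait_rows = {i: np.nonzero(trait_of_obs == i)[0]
                  for i in range(len(spec.traits))}

    Zc_all, n_levels_all, Kinv_all, Ksolve_all, logdetK_all = [], [], [], [], []
    for term in spec.random:
        if term.structure == "pedigree":
            n_lev = len(ped)
            Kinv = compute_A_inverse(ped).tocsc()
            lu = splu(Kinv, permc_spec="MMD_AT_PLUS_A")
            Ksolve = lu.solve
            ldK = log_det_A(ped)
            level_of = lambda vals: np.array(
                [ped.index_of(v) for v in vals], dtype=int
            )
        else:
            # shared level dictionary across the term's channels
            allvals = []
            for ch in term.channels:
                i = trait_index[ch.trait]
                df = tables[spec.traits[i].table]
                if spec.traits[i].subset:
                    df = df.query(spec.traits[i].subset)
                df = df.loc[obs_rows[trait_rows[i]]]
                allvals.append(df[ch.incidence].astype(str))
            levels = pd.unique(pd.concat(allvals, ignore_index=True))
            lut = {v: j for j, v in enumerate(levels)}
            n_lev = len(levels)
            Kinv, Ksolve, ldK = None, (lambda v: v), 0.0
            level_of = lambda vals, lut=lut: np.array(
                [lut[v] for v in vals], dtype=int
            )
        Zs = []
        for ch in term.channels:
            if ch.trait not in trait_index:
                raise ModelError(f"channel trait {ch.trait!r} not in model")
            i = trait_index[ch.trait]
            rows = trait_rows[i]
            ts = spec.traits[i]
            df = tables[ts.table]
            if ts.subset:
                df = df.query(ts.subset)
            df = df.loc[obs_rows[rows]]
            if ch.incidence not in df.columns:
                raise ModelError(
                    f"incidence column {ch.incidence!r} absent for term "
                    f"{term.name!r}"
                )
            lev = level_of(df[ch.incidence].astype(str).to_numpy())
            Z = sp.csr_matrix(
                (np.ones(len(rows)), (rows, lev)), shape=(n_obs, n_lev)
            )
            Zs.append(Z)
        Zc_all.append(Zs)
        n_levels_all.append(n_lev)
        Kinv_all.append(Kinv)
        Ksolve_all.append(Ksolve)
        logdetK_all.append(ldK)

    # residual structure: co-observed trait pairs share a unit
    resid_pairs = {}
    nt = len(spec.traits)
    resid_free = np.eye(nt, dtype=bool)
    resid_groups = []
    for i in range(nt):
        for j in range(i + 1, nt):
            ui = dict(zip(unit_keys[i], trait_rows[i]))
            shared = [(ui[k], trait_rows[j][m])
                      for m, k in enumerate(unit_keys[j]) if k in ui]
            if shared:
                oi = np.array([s[0] for s in shared])
                oj = np.array([s[1] for s in shared])
                resid_pairs[(i, j)] = (oi, oj)
                resid_free[i, j] = resid_free[j, i] = True
    if resid_pairs:
        all_units = np.concatenate(unit_keys)
        grouped = pd.Series(np.arange(n_obs)).groupby(all_units)
        resid_groups = [idx.to_numpy() for _, idx in grouped
                        if len(idx) > 1]

    return DesignBundle(
        y=y, trait_of_obs=trait_of_obs, X=sp.csr_matrix(X),
        fixed_cols=fixed_cols, terms=list(spec.random), Zc=Zc_all,
        n_levels=n_levels_all, Kinv=Kinv_all, K_solve=Ksolve_all,
        logdetK=logdetK_all, resid_pairs=resid_pairs, resid_free=resid_free,
        resid_groups=resid_groups, n_traits=nt,
        trait_names=[ts.name for ts in spec.traits], spec=spec,
        obs_table_row=obs_rows, x_rank=x_rank,
        W=sp.hstack([sp.csr_matrix(X)]
                    + [Z for Zs in Zc_all for Z in Zs]).tocsr(),
    )


# ---------------------------------------------------------------------------
# parameter bookkeeping


class _ParamMap:
    """Flat vector <-> {term covariance matrices, residual matrix}."""

    def __init__(self, design: DesignBundle, resid_fixed_value=None,
                 resid_all_fixed=False):
        self.design = design
        self.entries = []        # (kind, term_idx, i, j)
        for k, term in enumerate(design.terms):
            nc = term.n_channels
            fixed = term.fixed if term.fixed is not None \
                else np.zeros((nc, nc), bool)
            for i in range(nc):
                for j in range(i, nc):
                    if not fixed[i, j]:
                        self.entries.append(("term", k, i, j))
        nt = design.n_traits
        self.resid_fixed_value = resid_fixed_value
        for i in range(nt):
            for j in range(i, nt):
                if resid_all_fixed:
                    continue
                if design.resid_free[i, j]:
                    self.entries.append(("resid", None, i, j))
        self.n = len(self.entries)

    def labels(self):
        out = []
        for kind, k, i, j in self.entries:
            if kind == "term":
                t = self.design.terms[k]
                ci, cj = t.channels[i].trait, t.channels[j].trait
                out.append(f"{t.name}[{ci},{cj}]" if i != j
                           else f"{t.name}[{ci}]")
            else:
                ti = self.design.trait_names[i]
                tj = self.design.trait_names[j]
                out.append(f"residual[{ti},{tj}]" if i != j
                           else f"residual[{ti}]")
        return out

    def to_mats(self, theta):
        design = self.design
        mats = []
        for k, term in enumerate(design.terms):
            nc = term.n_channels
            m = np.array(term.start, float) if term.start is not None \
                else np.zeros((nc, nc))
            mats.append(m)
        nt = design.n_traits
        if self.resid_fixed_value is not None:
            R = np.array(self.resid_fixed_value, float)
        else:
            R = np.eye(nt)
        for val, (kind, k, i, j) in zip(theta, self.entries):
            if kind == "term":
                mats[k][i, j] = mats[k][j, i] = val
            else:
                R[i, j] = R[j, i] = val
        return mats, R

    def from_mats(self, mats, R):
        out = np.empty(self.n)
        for m, (kind, k, i, j) in enumerate(self.entries):
            out[m] = mats[k][i, j] if kind == "term" else R[i, j]
        return out

    def clamp(self, theta):
        """Floor variances; shrink covariances into the PSD cone."""
        theta = theta.copy()
        boundary = False
        for m, (kind, k, i, j) in enumerate(self.entries):
            if i == j and theta[m] < VAR_FLOOR:
                theta[m] = VAR_FLOOR
                boundary = True
        mats, R = self.to_mats(theta)
        for trial in range(60):
            ok = all(np.linalg.eigvalsh(m).min() > -1e-10 for m in mats) \
                and np.linalg.eigvalsh(R).min() > 1e-12
            if ok:
                break
            for m, (kind, k, i, j) in enumerate(self.entries):
                if i != j:
                    theta[m] *= 0.9
            mats, R = self.to_mats(theta)
        return theta, boundary


# ---------------------------------------------------------------------------
# likelihood machinery


class _MME:
    """Assembled mixed-model equations for one parameter vector."""

    def __init__(self, design: DesignBundle, mats, Rmat, weights=None):
        self.design = design
        d = design
        n_obs = len(d.y)
        nt = d.n_traits
        tro = d.trait_of_obs

        # R^-1 sparse; start from diagonal then correct co-observed blocks
        rdiag = np.array([Rmat[t, t] for t in range(nt)])[tro]
        if weights is not None:
            rdiag = rdiag / weights
        if d.resid_groups:
            # units observed for several traits get dense residual blocks
            rows, cols, vals = [], [], []
            handled = np.zeros(n_obs, bool)
            logdet = 0.0
            for grp in d.resid_groups:
                tr = tro[grp]
                blk = Rmat[np.ix_(tr, tr)]
                binv = np.linalg.inv(blk)
                logdet += math.log(np.linalg.det(blk))
                for a in range(len(grp)):
                    for b in range(len(grp)):
                        rows.append(grp[a])
                        cols.append(grp[b])
                        vals.append(binv[a, b])
                handled[grp] = True
            free = np.nonzero(~handled)[0]
            rows = np.concatenate([np.asarray(rows, int), free])
            cols = np.concatenate([np.asarray(cols, int), free])
            vals = np.concatenate([np.asarray(vals, float),
                                   1.0 / rdiag[free]])
            self.Rinv = sp.csr_matrix((vals, (rows, cols)),
                                      shape=(n_obs, n_obs))
            self.logdetR = logdet + float(np.sum(np.log(rdiag[free])))
        else:
            self.Rinv = sp.diags(1.0 / rdiag).tocsr()
            self.logdetR = float(np.sum(np.log(rdiag)))

        # G^-1 blocks (channel-major kron)
        self.p = d.X.shape[1]
        Ginv_blocks = [sp.csr_matrix((self.p, self.p))]
        logdetG = 0.0
        for k, term in enumerate(d.terms):
            Sk = mats[k]
            nc = term.n_channels
            q = d.n_levels[k]
            ev = np.linalg.eigvalsh(Sk)
            if ev.min() <= 0:
                Sk = Sk + np.eye(nc) * (abs(ev.min()) + 1e-10)
            Skinv = np.linalg.inv(Sk)
            Kinv = d.Kinv[k] if d.Kinv[k] is not None else sp.eye(q)
            Ginv_blocks.append(sp.kron(sp.csr_matrix(Skinv), Kinv))
            sign, ld = np.linalg.slogdet(Sk)
            logdetG += q * ld + nc * d.logdetK[k]
        self.W = d.W
        WtRi = (self.W.T @ self.Rinv).tocsr()
        C = (WtRi @ self.W) + sp.block_diag(Ginv_blocks)
        self.C = C.tocsc()
        self.rhs = WtRi @ d.y
        self.WtRi = WtRi
        self.logdetG = logdetG
        self.lu = splu(self.C, permc_spec="MMD_AT_PLUS_A")
        self.sol = self.lu.solve(self.rhs)
        self.logdetC = float(np.sum(np.log(np.abs(self.lu.U.diagonal()))))
        self.yPy = float(d.y @ (self.Rinv @ d.y) - self.sol @ self.rhs)

    def neg2_reml(self):
        return self.logdetC + self.logdetR + self.logdetG + self.yPy

    def project(self, f):
        """P f = R^-1 (f - W C^-1 W' R^-1 f)."""
        g = self.WtRi @ f
        return self.Rinv @ f - self.WtRi.T @ self.lu.solve(g)

    def Py(self):
        return self.Rinv @ self.design.y - self.WtRi.T @ self.sol


def _neg2ll(design, pmap, theta, weights):
    mats, R = pmap.to_mats(theta)
    try:
        mme = _MME(design, mats, R, weights)
    except RuntimeError:
        return np.inf, None
    v = mme.neg2_reml()
    if not np.isfinite(v):
        return np.inf, None
    return v, mme


def _dV_product(design, mme, entry, vec, weights):
    """(dV/dtheta) @ vec for one parameter entry."""
    kind, k, i, j = entry
    d = design
    if kind == "term":
        term = d.terms[k]
        Zi, Zj = d.Zc[k][i], d.Zc[k][j]
        Ksolve = d.K_solve[k]
        out = Zi @ Ksolve(Zj.T @ vec)
        if i != j:
            out = out + Zj @ Ksolve(Zi.T @ vec)
        return out
    # residual entry
    out = np.zeros_like(vec)
    if i == j:
        rows = np.nonzero(d.trait_of_obs == i)[0]
        w = 1.0 if weights is None else weights[rows]
        out[rows] = vec[rows] / w
    else:
        oi, oj = d.resid_pairs[(i, j)]
        out[oi] += vec[oj]
        out[oj] += vec[oi]
    return out


def _ai_matrix(design, mme, pmap, weights):
    Py = mme.Py()
    fs = [_dV_product(design, mme, e, Py, weights) for e in pmap.entries]
    Pfs = [mme.project(f) for f in fs]
    n = pmap.n
    AI = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            AI[a, b] = AI[b, a] = 0.5 * float(fs[a] @ Pfs[b])
    return AI


def _default_start(design: DesignBundle, pmap: _ParamMap):
    vy = np.array([
        np.var(design.y[design.trait_of_obs == t]) or 1.0
        for t in range(design.n_traits)
    ])
    n_parts = len(design.terms) + 1
    mats = []
    for term in design.terms:
        nc = term.n_channels
        m = np.zeros((nc, nc))
        for i in range(nc):
            ti = design.trait_names.index(term.channels[i].trait)
            m[i, i] = vy[ti] / (n_parts + 1)
        mats.append(m)
    R = np.diag(vy * 0.6)
    return mats, R


def reml_fit(design: DesignBundle, start: VarianceComponents | None = None,
             weights=None, resid_fixed=None, max_iter=200, tol=1e-6,
             verbose=False) -> FitResult:
    """AI-REML for the assembled design.

    ``resid_fixed``: residual covariance matrix held constant (threshold
    convention / PQL working scale).  ``weights``: per-observation residual
    weights (R_ii = sigma2_e / w_i).
    """
    pmap = _ParamMap(design, resid_fixed_value=resid_fixed,
                     resid_all_fixed=resid_fixed is not None)
    if start is not None:
        mats0 = [np.array(start.terms[t.name][1], float)
                 for t in design.terms]
        R0 = np.array(start.residual, float)
    else:
        mats0, R0 = _default_start(design, pmap)
    for term, m in zip(design.terms, mats0):
        term.start = m          # baseline values for fixed entries
    theta = pmap.from_mats(mats0, R0)
    theta, _ = pmap.clamp(theta)

    if pmap.n == 0:
        f2, mme = _neg2ll(design, pmap, theta, weights)
        return _package_fit(design, pmap, theta, mme, -0.5 * f2, True, False,
                            0, [], None)

    f2, mme = _neg2ll(design, pmap, theta, weights)
    trace = [(-0.5 * f2, theta.copy())]
    converged = False
    boundary = False
    it = 0
    scale = np.maximum(np.abs(theta), 1e-4)
    for it in range(1, max_iter + 1):
        # numerical score of log-likelihood (exact function, central diff)
        grad = np.empty(pmap.n)
        h = 1e-5 * np.maximum(np.abs(theta), 1e-3 * scale)
        for m in range(pmap.n):
            tp = theta.copy(); tp[m] += h[m]
            tm = theta.copy(); tm[m] -= h[m]
            fp, _ = _neg2ll(design, pmap, tp, weights)
            fm, _ = _neg2ll(design, pmap, tm, weights)
            grad[m] = -0.5 * (fp - fm) / (2 * h[m])
        AI = _ai_matrix(design, mme, pmap, weights)
        try:
            delta = np.linalg.solve(
                AI + np.eye(pmap.n) * 1e-8 * max(AI.max(), 1.0), grad
            )
        except np.linalg.LinAlgError:
            delta = grad / np.maximum(np.diag(AI), 1e-8)
        step = 1.0
        accepted = False
        for _ in range(40):
            cand, bnd = pmap.clamp(theta + step * delta)
            fc, mme_c = _neg2ll(design, pmap, cand, weights)
            if fc <= f2 + 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True   # no ascent direction left: local optimum
            break
        move = np.max(np.abs(cand - theta) / (np.abs(theta) + 1.0))
        theta, f2, mme = cand, fc, mme_c
        boundary = boundary or bnd
        trace.append((-0.5 * f2, theta.copy()))
        if move < tol:
            converged = True
            break

    AI = _ai_matrix(design, mme, pmap, weights)
    try:
        samp_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        samp_cov = np.linalg.pinv(AI)
    return _package_fit(design, pmap, theta, mme, -0.5 * f2, converged,
                        boundary, it, trace, samp_cov)


def _package_fit(design, pmap, theta, mme, ll, converged, boundary, it,
                 trace, samp_cov):
    mats, R = pmap.to_mats(theta)
    terms = {}
    off = design.X.shape[1]
    u = {}
    for k, term in enumerate(design.terms):
        labels = [f"{c.trait}@{c.incidence}" for c in term.channels]
        terms[term.name] = (labels, mats[k])
        q = design.n_levels[k]
        u[term.name] = mme.sol[off:off + term.n_channels * q].reshape(
            term.n_channels, q
        )
        off += term.n_channels * q
    vc = VarianceComponents(
        terms=terms, residual=R, trait_names=design.trait_names,
        sampling_cov=samp_cov, free_labels=pmap.labels(),
    )
    p = design.X.shape[1]
    beta = mme.sol[:p]
    # C^-1 fixed-effect block via p unit-vector solves (p is small)
    E = np.zeros((mme.C.shape[0], p))
    E[:p, :p] = np.eye(p)
    beta_cov = np.vstack([mme.lu.solve(E[:, j])[:p] for j in range(p)]).T
    return FitResult(
        spec=design.spec, varcomp=vc, loglik=ll, beta=beta,
        beta_cov=beta_cov, fixed_cols=design.fixed_cols, u=u,
        converged=converged, boundary=boundary, n_iter=it, trace=trace,
        design=design, n_obs=len(design.y),
    )


# ---------------------------------------------------------------------------
# threshold (logit) model via penalized quasi-likelihood


def fit_threshold_trait(design: DesignBundle, start=None, max_outer=4,
                        outer_tol=1e-4, method="laplace") -> FitResult:
    """Single-trait threshold model with a logit link.

    A short penalized quasi-likelihood phase (linear mixed model on the
    working variate, working-scale residual fixed at 1.0) provides starting
    values; the variance components are then re-estimated by maximizing the
    Laplace-approximate marginal likelihood (fixed effects integrated out),
    which markedly reduces the downward bias of plain PQL for binary data.
    Reported components sit on the logistic liability scale, where the
    residual contributes pi^2/3 to the phenotypic variance.
    """
    y = design.y
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ModelError("threshold trait response must be coded 0/1")
    if y.min() == y.max():
        raise ModelError("response is constant (all 0 or all 1)")
    _check_separation(design)

    eta = np.log((y.mean() + 0.02) / (1 - y.mean() + 0.02)) * np.ones_like(y)
    fit = None
    resid_fixed = np.array([[1.0]])
    vc = start
    for outer in range(max_outer):
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-6, 1 - 1e-6)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        old_y = design.y
        design.y = z
        fit = reml_fit(design, start=vc, resid_fixed=resid_fixed, weights=w,
                       max_iter=40 if outer == 0 else 15)
        design.y = old_y
        vc = fit.varcomp
        eta_new = _linear_predictor(fit, design)
        delta = np.max(np.abs(eta_new - eta)) if len(eta) else 0.0
        eta = eta_new
        if delta < outer_tol:
            break
    fit.converged = fit.converged and delta < 10 * outer_tol
    if method == "laplace":
        fit = _laplace_refine(design, fit, eta)
    return fit


def _inner_mode(design, pmap, theta, eta, max_iter=60, tol=1e-8):
    """Penalized IRLS for the joint (beta, u) mode at fixed variances."""
    y = design.y
    mats, R = pmap.to_mats(theta)
    mme = None
    for _ in range(max_iter):
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-9, 1 - 1e-9)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        design.y = z
        try:
            mme = _MME(design, mats, R, weights=w)
        finally:
            design.y = y
        eta_new = np.asarray(design.W @ mme.sol).ravel()
        step = np.max(np.abs(eta_new - eta))
        eta = eta_new
        if step < tol:
            break
    return mme, eta


def _laplace_objective(design, pmap, theta, eta0):
    """Negative Laplace-approximate restricted log-likelihood."""
    y = design.y
    mats, _ = pmap.to_mats(theta)
    mme, eta = _inner_mode(design, pmap, theta, eta0)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    bern = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
    # quadratic penalty u' G^-1 u and log|G|
    off = design.X.shape[1]
    pen = 0.0
    logdetG = 0.0
    for k, term in enumerate(design.terms):
        q = design.n_levels[k]
        nc = term.n_channels
        u = mme.sol[off:off + nc * q].reshape(nc, q)
        off += nc * q
        Sk = mats[k]
        ev = np.linalg.eigvalsh(Sk)
        if ev.min() <= 0:
            Sk = Sk + np.eye(nc) * (abs(ev.min()) + 1e-10)
        Skinv = np.linalg.inv(Sk)
        Kinv = design.Kinv[k]
        Ku = (np.vstack([Kinv @ u[c] for c in range(nc)])
              if Kinv is not None else u)
        pen += float(np.sum(Skinv * (u @ Ku.T)))
        logdetG += q * np.linalg.slogdet(Sk)[1] + nc * design.logdetK[k]
    f = bern - 0.5 * pen - 0.5 * logdetG - 0.5 * mme.logdetC
    return -f, eta


def _laplace_refine(design, fit: FitResult, eta):
    from scipy.optimize import minimize

    pmap = _ParamMap(design, resid_fixed_value=np.array([[1.0]]),
                     resid_all_fixed=True)
    mats0 = [np.array(fit.varcomp.terms[t.name][1], float)
             for t in design.terms]
    theta0 = pmap.from_mats(mats0, np.array([[1.0]]))
    theta0 = np.maximum(theta0, 1e-6)
    diag = np.array([i == j for _, _, i, j in pmap.entries])
    if not diag.all():
        return fit          # covariance terms: keep the PQL estimates
    state = {"eta": eta}

    def nll(logtheta):
        theta = np.exp(np.clip(logtheta, -18, 6))
        v, eta_new = _laplace_objective(design, pmap, theta, state["eta"])
        state["eta"] = eta_new
        return v

    res = minimize(nll, np.log(theta0), method="Nelder-Mead",
                   options=dict(xatol=2e-3, fatol=5e-4, maxiter=80))
    theta = np.exp(res.x)
    # sampling covariance from a finite-difference Hessian in theta
    n = pmap.n
    H = np.zeros((n, n))
    f0 = nll(np.log(theta))
    h = 0.05 * np.maximum(theta, 1e-4)
    for a in range(n):
        for b in range(a, n):
            ta = theta.copy(); ta[a] += h[a]
            tb = theta.copy(); tb[b] += h[b]
            tab = theta.copy(); tab[a] += h[a]; tab[b] += h[b]
            fa, _ = _laplace_objective(design, pmap, ta, state["eta"])
            fb, _ = _laplace_objective(design, pmap, tb, state["eta"])
            fab, _ = _laplace_objective(design, pmap, tab, state["eta"])
            H[a, b] = H[b, a] = (fab - fa - fb + f0) / (h[a] * h[b])
    try:
        samp_cov = np.linalg.inv(H)
        if np.diag(samp_cov).min() <= 0:
            samp_cov = np.linalg.pinv(np.abs(H))
    except np.linalg.LinAlgError:
        samp_cov = np.linalg.pinv(H)

    mme, eta = _inner_mode(design, pmap, theta, state["eta"])
    out = _package_fit(design, pmap, theta, mme, -f0, res.success
                       or res.status == 2, bool((theta <= 2e-6).any()),
                       fit.n_iter + res.nit, fit.trace, samp_cov)
    return out


def _linear_predictor(fit: FitResult, design: DesignBundle):
    eta = design.X @ fit.beta
    for k, term in enumerate(design.terms):
        for c, Z in enumerate(design.Zc[k]):
            eta = eta + Z @ fit.u[term.name][c]
    return np.asarray(eta).ravel()


def _check_separation(design: DesignBundle):
    y = design.y
    X = design.X.toarray()
    for (trait, fac), (a, b) in design.fixed_cols.items():
        if fac == "intercept":
            continue
        groups = [X[:, j] > 0 for j in range(a, b)]
        groups.append(~np.any(X[:, a:b] > 0, axis=1))   # reference level
        for sel in groups:
            if sel.sum() >= 5 and y[sel].min() == y[sel].max():
                raise ModelError(
                    f"complete separation: factor {fac!r} has a level "
                    "with an all-equal binary response"
                )


# ---------------------------------------------------------------------------
# fixed-effect tests


def wald_f_test(fit: FitResult, trait: str, factor: str):
    """Wald F for dropping one fixed factor from the fitted model.

    Denominator degrees of freedom use a containment-style approximation
    (residual observations minus fixed-effect rank).
    """
    key = (trait, factor)
    if key not in fit.fixed_cols:
        raise ModelError(f"factor {factor!r} not in fitted model for {trait}")
    a, b = fit.fixed_cols[key]
    q = b - a
    if q == 0:
        raise ModelError(f"factor {factor!r} absorbed by constraints")
    bvec = fit.beta[a:b]
    V = fit.beta_cov[a:b, a:b]
    F = float(bvec @ np.linalg.solve(V, bvec)) / q
    ddf = max(fit.n_obs - fit.design.x_rank, 1)
    p = float(stats.f.sf(F, q, ddf))
    return F, q, ddf, p


def stepwise_select(spec: ModelSpec, ped: Pedigree, pheno, alpha=0.05,
                    fitter=None) -> ModelSpec:
    """Backward elimination of fixed factors by Wald-F p-value.

    Refits after each drop; stops when every retained factor has p < alpha.
    """
    import copy

    spec = copy.deepcopy(spec)
    fitter = fitter or (lambda d: reml_fit(d))
    while True:
        candidates = [(ts.name, f) for ts in spec.traits for f in ts.fixed]
        if not candidates:
            return spec
        design = build_design(spec, ped, pheno)
        fit = fitter(design)
        worst, worst_p = None, alpha
        for trait, fac in candidates:
            _, _, _, p = wald_f_test(fit, trait, fac)
            if p >= worst_p:
                worst, worst_p = (trait, fac), p
        if worst is None:
            return spec
        for ts in spec.traits:
            if ts.name == worst[0]:
                ts.fixed = [f for f in ts.fixed if f != worst[1]]


# ---------------------------------------------------------------------------
# convenience model builders


def animal_term(traits, fixed=None, start=None):
    """Multi-trait additive genetic term (A-structured, animal incidence)."""
    chs = [Channel(t, "animal_id") for t in traits]
    return RandomTerm("additive", "pedigree", chs, start=start, fixed=fixed)


def litter_term(traits, start=None, fixed=None):
    chs = [Channel(t, "litter") for t in traits]
    return RandomTerm("litter", "iid", chs, start=start, fixed=fixed)


def disease_spec(trait: str, environment: str, fixed=("batch", "sex"),
                 response: str | None = None) -> ModelSpec:
    """Single-trait threshold model for one disorder in one environment."""
    name = f"{trait}_{environment}"
    fx = list(fixed) + (["farm"] if environment == "Ch" else [])
    ts = TraitSpec(name=name, response=response or trait, table="animals",
                   fixed=fx, subset=f"environment == '{environment}'")
    return ModelSpec(
        traits=[ts],
        random=[animal_term([name]), litter_term([name])],
        link="logit-threshold",
    )


def ww_spec(fixed=("batch", "sex", "parity")) -> ModelSpec:
    """Weaning weight: direct + maternal genetic (rearing dam), common
    litter and maternal environmental terms."""
    fx = [f for f in fixed]
    ts = TraitSpec(name="WW", response="WW", table="animals", fixed=fx)
    genetic = RandomTerm(
        "additive", "pedigree",
        [Channel("WW", "animal_id"), Channel("WW", "rearing_dam_id")],
    )
    return ModelSpec(
        traits=[ts],
        random=[
            genetic,
            litter_term(["WW"]),
            RandomTerm("maternal_env", "iid",
                       [Channel("WW", "rearing_dam_id")]),
        ],
    )


def nba_spec(fixed=("year_season", "parity_status")) -> ModelSpec:
    """Litter size of the doe with permanent environmental effect."""
    ts = TraitSpec(name="NBA", response="NBA", table="litters",
                   fixed=list(fixed), unit="litter")
    return ModelSpec(
        traits=[ts],
        random=[
            RandomTerm("additive", "pedigree", [Channel("NBA", "dam_id")]),
            RandomTerm("perm_env", "iid", [Channel("NBA", "dam_id")]),
        ],
    )


def bivariate_cross_env_spec(trait: str, fixed=("batch", "sex")) -> ModelSpec:
    """Linear bivariate model treating S and Ch expressions as two traits.

    No animal holds records in both environments, so the residual covariance
    between them is structurally fixed at zero (the design builder detects
    the absence of co-observed units and freezes the entry).
    """
    t_s = TraitSpec(name=f"{trait}_S", response=trait, table="animals",
                    fixed=list(fixed), subset="environment == 'S'")
    t_c = TraitSpec(name=f"{trait}_Ch", response=trait, table="animals",
                    fixed=list(fixed) + ["farm"],
                    subset="environment == 'Ch'")
    names = [t_s.name, t_c.name]
    return ModelSpec(
        traits=[t_s, t_c],
        random=[animal_term(names), litter_term(names)],
    )
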