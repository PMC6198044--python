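"""Pedigree ingestion, numerator relationship matrix (A), sparse A-inverse,
and the rearing-dam reassignment rule for cross-fostered kits.

The numerator relationship matrix is built by the tabular method; its inverse
is assembled directly from pedigree rules using Mendelian-sampling variances
that account for parental inbreeding (Meuwissen & Luo style coefficients), so
the two routes agree for arbitrarily deep, inbred pedigrees.

Animals are remapped to dense integer indices internally (parents always
precede offspring); external outputs are indexed by the original ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1
#: field values treated as "parent unknown" in pedigree files
UNKNOWN_SENTINELS = {"", "0", "na", "nan", "none", "."}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing ids...)."""


@dataclass
class Pedigree:
    """A validated pedigree in topological order (parents before offspring).

    ``sire``/``dam`` hold dense integer indices into ``ids`` (``-1`` =
    unknown founder parent).  ``rearing_dam`` follows the biological dam
    unless :func:`assign_rearing_effects` reassigned a fostered kit; the
    additive relationship structure always follows the biological parents.
    """

    ids: np.ndarray            # original identifiers, object dtype
    sire: np.ndarray           # int index or UNKNOWN
    dam: np.ndarray            # int index or UNKNOWN
    sex: np.ndarray            # 'M'/'F'
    batch: np.ndarray = None
    environment: np.ndarray = None  # 'S'/'Ch'
    rearing_dam: np.ndarray = None
    litter: np.ndarray = None  # rearing-litter labels (int), -1 if none
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        n = len(self.ids)
        if self.batch is None:
            self.batch = np.zeros(n, dtype=int)
        if self.environment is None:
            self.environment = np.array(["S"] * n, dtype=object)
        if self.rearing_dam is None:
            self.rearing_dam = self.dam.copy()
        if self.litter is None:
            # default: one rearing litter per (biological) dam
            self.litter = self.dam.copy()
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_sires(self) -> int:
        return len(np.unique(self.sire[self.sire >= 0]))

    @property
    def n_dams(self) -> int:
        return len(np.unique(self.dam[self.dam >= 0]))

    def index_of(self, animal_id) -> int:
        return self._index[animal_id]

    def to_frame(self) -> pd.DataFrame:
        def _name(idx):
            return np.where(idx >= 0, self.ids[np.maximum(idx, 0)], "0")

        return pd.DataFrame(
            {
                "animal_id": self.ids,
                "sire_id": _name(self.sire),
                "dam_id": _name(self.dam),
                "sex": self.sex,
                "birth_batch": self.batch,
                "environment": self.environment,
                "rearing_dam_id": _name(self.rearing_dam),
            }
        )


def _toposort(ids, sire, dam):
    """Return a parent-before-offspring ordering; raise on cycles."""
    n = len(ids)
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    order = [i for i in range(n) if indeg[i] == 0]
    head = 0
    while head < len(order):
        i = order[head]
        head += 1
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
    if len(order) != n:
        bad = ids[int(np.nonzero(indeg > 0)[0][0])]
        raise PedigreeError(
            f"pedigree contains a cycle involving animal {bad!r}"
        )
    return np.asarray(order, dtype=int)


def load_pedigree(path) -> Pedigree:
    """Read a delimited pedigree file (comma or tab, auto-detected).

    Required columns: ``animal_id``, ``sire_id``, ``dam_id``, ``sex``.
    Optional: ``birth_batch``, ``environment``, ``rearing_dam_id``,
    ``litter``.  Unknown parents are coded by an empty field or ``0``.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    required = ["animal_id", "sire_id", "dam_id", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree file lacks columns {missing}")
    return pedigree_from_frame(df)


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    ids = df["animal_id"].astype(str).to_numpy(dtype=object)
    if len(ids) != len(set(ids)):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise PedigreeError(f"duplicate animal id {dup!r}")
    index = {a: i for i, a in enumerate(ids)}

    def parent_col(col):
        out = np.full(len(ids), UNKNOWN, dtype=int)
        for row, raw in enumerate(df[col].astype(str)):
            v = raw.strip()
            if v.lower() in UNKNOWN_SENTINELS:
                continue
            if v not in index:
                raise PedigreeError(
                    f"line {row + 2}: {col} {v!r} is not a listed animal"
                )
            out[row] = index[v]
        return out

    sire = parent_col("sire_id")
    dam = parent_col("dam_id")
    sex = df["sex"].astype(str).str.strip().to_numpy(dtype=object)
    for row, s in enumerate(sex):
        if s not in ("M", "F"):
            raise PedigreeError(f"line {row + 2}: unknown sex {s!r}")
    for row in range(len(ids)):
        if sire[row] == row or dam[row] == row:
            raise PedigreeError(
                f"pedigree contains a cycle involving animal {ids[row]!r}"
            )

    order = _toposort(ids, sire, dam)
    remap = np.empty(len(ids), dtype=int)
    remap[order] = np.arange(len(ids))

    def reindex_parents(col):
        out = col[order]
        return np.where(out >= 0, remap[np.maximum(out, 0)], UNKNOWN)

    kw = {}
    if "birth_batch" in df.columns:
        kw["batch"] = df["birth_batch"].to_numpy(dtype=object)[order]
    if "environment" in df.columns:
        kw["environment"] = df["environment"].to_numpy(dtype=object)[order]
    if "rearing_dam_id" in df.columns:
        rd = parent_col("rearing_dam_id")
        kw["rearing_dam"] = reindex_parents(rd)
    if "litter" in df.columns:
        lit = pd.factorize(df["litter"].astype(str))[0]
        kw["litter"] = lit[order]
    return Pedigree(
        ids=ids[order],
        sire=reindex_parents(sire),
        dam=reindex_parents(dam),
        sex=sex[order],
        **kw,
    )


def compute_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    ``A[i, i] = 1 + F_i`` with ``F_i`` the inbreeding coefficient; founders
    (both parents unknown) have ``F = 0`` and are mutually unrelated.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (founders 0).

    Meuwissen & Luo ancestor walk on the L D L' decomposition of A:
    ``a_ii = sum_j L_ij^2 d_j`` accumulated over the ancestor set of i,
    which costs O(ancestors^2) per animal instead of a dense tabular pass.
    """
    import heapq

    n = len(ped)
    F = np.zeros(n)
    d = np.ones(n)
    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        if s >= 0 and dm >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s >= 0 or dm >= 0:
            d[i] = 0.75 - 0.25 * F[s if s >= 0 else dm]
        if s < 0 and dm < 0:
            continue
        L = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            if j not in L:
                continue
            lj = L.pop(j)
            aii += lj * lj * d[j]
            for p in (ped.sire[j], ped.dam[j]):
                if p >= 0:
                    if p not in L:
                        heapq.heappush(heap, -p)
                        L[p] = 0.0
                    L[p] += 0.5 * lj
        F[i] = aii - 1.0
    return F


def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None):
    """Within-family (Mendelian sampling) variance coefficients d_i.

    d_i = 0.5 - 0.25 (F_s + F_d) when both parents known, 0.75 - 0.25 F_p
    with one known parent, and 1 for founders.
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    n = len(ped)
    d = np.ones(n)
    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        if s >= 0 and dm >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s >= 0 or dm >= 0:
            p = s if s >= 0 else dm
            d[i] = 0.75 - 0.25 * F[p]
    return d


def compute_A_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A assembled directly from pedigree rules.

    Uses A^-1 = (I - 0.5 P)' D^-1 (I - 0.5 P) with P the parent incidence
    and D the (inbreeding-aware) Mendelian variances, i.e. Henderson's rules
    including inbreeding.
    """
    n = len(ped)
    d = mendelian_variances(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        rows.append(i)
        cols.append(i)
        vals.append(1.0)
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                rows.append(i)
                cols.append(p)
                vals.append(-0.5)
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Dinv = sp.diags(1.0 / d)
    return (L.T @ Dinv @ L).tocsr()


def log_det_A(ped: Pedigree) -> float:
    """log |A| = sum(log d_i); cheap byproduct of the pedigree decomposition."""
    return float(np.sum(np.log(mendelian_variances(ped))))


def assign_rearing_effects(ped: Pedigree, fostering) -> Pedigree:
    """Reassign maternal and common-litter incidence of fostered kits.

    ``fostering`` is an iterable of ``(kit_id, adoptive_dam_id)`` pairs.  The
    maternal genetic, maternal environmental and common-litter effects of a
    fostered kit point to the adoptive suckling dam and her litter; the
    additive (direct) relationship still follows the biological pedigree.
    Returns a new :class:`Pedigree`; the input is not modified.
    """
    rearing = ped.rearing_dam.copy()
    litter = ped.litter.copy()
    for kit_id, adoptive_id in fostering:
        try:
            kit = ped.index_of(kit_id)
        except KeyError:
            raise PedigreeError(f"fostered kit {kit_id!r} is not in pedigree")
        try:
            adoptive = ped.index_of(adoptive_id)
        except KeyError:
            raise PedigreeError(
                f"adoptive dam {adoptive_id!r} is not in pedigree"
            )
        if ped.sex[adoptive] != "F":
            raise PedigreeError(f"adoptive dam {adoptive_id!r} is not female")
        rearing[kit] = adoptive
        # join the adoptive dam's rearing litter (new label if she has none)
        mates = np.nonzero((rearing == adoptive)
                           & (np.arange(len(ped)) != kit))[0]
        litter[kit] = litter[mates[0]] if len(mates) else litter.max() + 1
    return Pedigree(
        ids=ped.ids,
        sire=ped.sire,
        dam=ped.dam,
        sex=ped.sex,
        batch=ped.batch,
        environment=ped.environment,
        rearing_dam=rearing,
        litter=litter,
        _index=dict(ped._index),
    )
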