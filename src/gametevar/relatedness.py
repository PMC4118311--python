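"""Pedigree and genomic inbreeding, and base-population allele frequencies.

Genomic inbreeding F_G is the VanRaden genomic-relationship-matrix diagonal
minus one, computed against base-population allele frequencies p; those can
be taken as the mean gene content of genotyped pedigree founders or
estimated by the gene-content mixed model (gene content regressed on the
pedigree, p = intercept / 2).  Pedigree inbreeding F_P is half the additive
relationship between an animal's parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

UNKNOWN_PARENT = -1


@dataclass
class Pedigree:
    """Ancestry records; ``sire``/``dam`` are row indices (-1 = unknown)."""

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray = None
    sex: np.ndarray = None
    owner: np.ndarray = None

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        n = len(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate animal ids in pedigree")
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise ValueError("sire/dam arrays must match the id list")
        if self.birth_year is None:
            self.birth_year = np.zeros(n, dtype=np.int64)
        else:
            self.birth_year = np.asarray(self.birth_year, dtype=np.int64)
        if self.sex is None:
            self.sex = np.full(n, "U", dtype=object)
        else:
            self.sex = np.asarray(self.sex, dtype=object)
        if self.owner is None:
            self.owner = np.full(n, "", dtype=object)
        else:
            self.owner = np.asarray(self.owner, dtype=object)
        self._topo = self._topological_order()

    def _topological_order(self) -> np.ndarray:
        n = len(self.ids)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        order, stack = [], [i for i in range(n) if indeg[i] == 0]
        while stack:
            i = stack.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != n:
            raise ValueError("pedigree contains a cycle")
        return np.asarray(order, dtype=np.int64)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def topological_order(self) -> np.ndarray:
        """Indices ordered with parents before offspring."""
        return self._topo

    def index_of(self, animal_id: str) -> int:
        return self.ids.index(animal_id)

    def founders(self) -> np.ndarray:
        """Indices of animals with both parents unknown."""
        return np.flatnonzero((self.sire < 0) & (self.dam < 0))

    def to_frame(self) -> pd.DataFrame:
        def name(p):
            return "0" if p < 0 else self.ids[p]

        return pd.DataFrame(
            {"animal": self.ids,
             "sire": [name(s) for s in self.sire],
             "dam": [name(d) for d in self.dam],
             "birth_year": self.birth_year, "sex": self.sex, "owner": self.owner}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        ids = df["animal"].astype(str).tolist()
        pos = {a: i for i, a in enumerate(ids)}

        def idx(col):
            out = np.empty(len(ids), dtype=np.int64)
            for i, v in enumerate(df[col].astype(str)):
                if v in ("0", "", "nan", "NA"):
                    out[i] = UNKNOWN_PARENT
                elif v in pos:
                    out[i] = pos[v]
                else:
                    raise ValueError(f"parent {v!r} not in pedigree")
            return out

        return cls(
            ids, idx("sire"), idx("dam"),
            df["birth_year"].to_numpy() if "birth_year" in df else None,
            df["sex"].to_numpy() if "sex" in df else None,
            df["owner"].to_numpy() if "owner" in df else None,
        )


def pedigree_inbreeding(ped: Pedigree) -> np.ndarray:
    """F_P = kinship(sire, dam), by memoized kinship recursion in
    topological order; founders and animals with an unknown parent get 0."""
    sire, dam = ped.sire, ped.dam
    rank = np.empty(ped.n_animals, dtype=np.int64)
    rank[ped.topological_order] = np.arange(ped.n_animals)
    F = np.zeros(ped.n_animals)
    cache: dict[tuple[int, int], float] = {}

    def kin(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if rank[a] > rank[b]:
            a, b = b, a
        key = (a, b)
        v = cache.get(key)
        if v is not None:
            return v
        if a == b:
            v = 0.5 * (1.0 + F[a])
        else:
            v = 0.5 * (kin(sire[b], a) + kin(dam[b], a))
        cache[key] = v
        return v

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * ped.n_animals + 1000))
    try:
        for i in ped.topological_order:
            F[i] = kin(sire[i], dam[i])
    finally:
        sys.setrecursionlimit(old)
    return F


def genomic_inbreeding(dosages: np.ndarray, base_freqs: np.ndarray) -> np.ndarray:
    """F_G per animal from the genomic-relationship diagonal:

        g_ii = sum_k (m_ik - 2 p_k)^2 / (2 sum_k p_k (1 - p_k)),  F_G = g_ii - 1.
    """
    m = np.asarray(dosages, dtype=np.float64)
    p = np.asarray(base_freqs, dtype=np.float64)
    if m.ndim != 2 or m.shape[1] != p.shape[0]:
        raise ValueError("dosage matrix and frequency vector are inconsistent")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("base frequencies must lie strictly in (0, 1); "
                         "filter monomorphic SNPs first")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    g = ((m - 2.0 * p) ** 2).sum(axis=1) / denom
    return g - 1.0


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> csc_matrix:
    """Sparse inverse of the additive relationship matrix (Henderson's
    rules, with inbreeding when ``F`` is supplied)."""
    if F is None:
        F = pedigree_inbreeding(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(ped.n_animals):
        s, d = ped.sire[i], ped.dam[i]
        fs = F[s] if s >= 0 else 0.0
        fd = F[d] if d >= 0 else 0.0
        if s >= 0 and d >= 0:
            dii = 0.5 - 0.25 * (fs + fd)
        elif s >= 0 or d >= 0:
            dii = 0.75 - 0.25 * (fs if s >= 0 else fd)
        else:
            dii = 1.0
        w = 1.0 / dii
        add(i, i, w)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * w)
    n = ped.n_animals
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def base_allele_frequencies(
    dosages: np.ndarray,
    animal_ids: list,
    ped: Pedigree,
    mode: str = "founder-mean",
    variance_ratio: float = 0.01,
) -> np.ndarray:
    """Base-population allele frequencies from gene content.

    founder-mean
        Mean gene content of genotyped pedigree founders, divided by 2.
    gene-content-blup
        Per SNP, fit gene content c = mu + u with cov(u) proportional to
        the additive relationship matrix (variance ratio lambda =
        residual/additive, default 0.01) and return p = mu_hat / 2; all
        SNPs share one factorization of the mixed-model equations.
    """
    m = np.asarray(dosages, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != len(animal_ids):
        raise ValueError("dosage matrix must be animals x SNPs")
    if m.shape[0] == 0:
        raise ValueError("no genotyped animals")
    try:
        rows = np.array([ped.index_of(a) for a in animal_ids])
    except ValueError as e:
        raise ValueError("genotyped animals must be a subset of the pedigree") from e

    if mode == "founder-mean":
        fset = set(ped.founders().tolist())
        sel = np.flatnonzero([r in fset for r in rows])
        if sel.size == 0:
            raise ValueError("no genotyped founders for founder-mean mode")
        return m[sel].mean(axis=0) / 2.0
    if mode != "gene-content-blup":
        raise ValueError(f"unknown mode: {mode!r}")

    n = ped.n_animals
    ng, nsnp = m.shape
    Ainv = a_inverse(ped)
    # MME for c = 1 mu + Z u + e, Z selecting genotyped rows:
    # [ ng      1'Z          ] [mu]   [1'c ]
    # [ Z'1   Z'Z + lambda A^-1] [u ] = [Z'c]
    Z = coo_matrix((np.ones(ng), (np.arange(ng), rows)), shape=(ng, n)).tocsc()
    ZtZ = (Z.T @ Z).tocsc()
    top = np.concatenate([[ng], np.asarray(Z.sum(axis=0)).ravel()])
    C = coo_matrix((n + 1, n + 1)).tolil()
    C[0, :] = top
    C[1:, 0] = top[1:].reshape(-1, 1)
    C[1:, 1:] = ZtZ + variance_ratio * Ainv
    rhs = np.vstack([m.sum(axis=0), Z.T @ m])
    sol = splu(C.tocsc()).solve(rhs)
    return sol[0] / 2.0


def usable_snps(p: np.ndarray, lo: float = 0.01, hi: float = 0.99) -> np.ndarray:
    """Mask of SNPs whose base frequency is safely polymorphic for F_G."""
    p = np.asarray(p, dtype=np.float64)
    return (p > lo) & (p < hi)
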