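"""Cell-type neighborhood enrichment against a permutation null.

For each cell the k nearest neighbors (Euclidean distance between cell
centroids, default k = 10) define its neighborhood.  The observed statistic
for an ordered type pair (a, b) is the total count of type-b cells among the
neighbor lists of type-a cells.  The null distribution comes from permuting
the type labels over cells with the graph fixed (default 10,000
permutations); z-scores summarize enrichment/depletion and two-sided
permutation p-values (with add-one correction) are controlled with the
Benjamini-Hochberg procedure.

Enrichment is directional — (a, b) uses a's neighbor lists — so the z
matrix is not symmetrized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = ["NeighborGraph", "EnrichmentResult", "knn_graph", "neighborhood_enrichment", "bh_adjust"]


@dataclass
class NeighborGraph:
    """k-nearest-neighbor lists: (n, k) integer indices, no self-neighbors."""

    indices: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        n, k = self.indices.shape
        if k != self.k:
            raise ValueError("indices shape disagrees with k")
        if np.any(self.indices == np.arange(n)[:, None]):
            raise ValueError("self-neighbors are not allowed")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


@dataclass
class EnrichmentResult:
    """Type-pair enrichment z-scores with permutation p-values.

    Matrices are DataFrames indexed by source type (rows, whose neighbor
    lists are counted) and neighbor type (columns).  ``significant`` marks
    pairs with BH-adjusted p below ``alpha``; pairs with zero permutation
    variance are masked (NaN z and p).
    """

    z: pd.DataFrame
    pvalues: pd.DataFrame
    adj_pvalues: pd.DataFrame
    significant: pd.DataFrame
    observed: pd.DataFrame
    n_perm: int
    seed: int | None
    alpha: float


def knn_graph(centroids: np.ndarray, k: int = 10) -> NeighborGraph:
    """Exact Euclidean k-nearest neighbors of each centroid.

    Uses a kd-tree; equal distances are broken by the smaller index, so the
    result matches a brute-force O(n²) search.
    """
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    tree = cKDTree(pts)
    # query extra neighbors so ties at the k-boundary can be re-ordered
    m = min(n, k + 8)
    d, idx = tree.query(pts, k=m)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        cand_d, cand_i = d[i], idx[i]
        keep = cand_i != i
        cand_d, cand_i = cand_d[keep], cand_i[keep]
        order = np.lexsort((cand_i, cand_d))
        out[i] = cand_i[order][:k]
    return NeighborGraph(out, k)


def neighborhood_enrichment(
    types: np.ndarray | pd.Series,
    g: NeighborGraph,
    n_perm: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Permutation test of neighbor-type composition per ordered type pair.

    Deterministic under a fixed seed.  ``types`` must contain at least two
    distinct labels; ``n_perm`` at least 100.
    """
    labels = pd.Series(np.asarray(types, dtype=object))
    if len(labels) != g.n_cells:
        raise ValueError("one type label per cell required")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    codes, uniques = pd.factorize(labels, sort=True)
    t = len(uniques)
    if t < 2:
        raise ValueError("need at least 2 distinct cell types")

    nbr = g.indices
    n = g.n_cells

    def _pair_counts(code_vec: np.ndarray) -> np.ndarray:
        src = np.repeat(code_vec, g.k)
        dst = code_vec[nbr].ravel()
        return np.bincount(src * t + dst, minlength=t * t).reshape(t, t)

    obs = _pair_counts(codes).astype(float)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, t, t), dtype=np.float64)
    for p in range(n_perm):
        null[p] = _pair_counts(rng.permutation(codes))

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    dev = np.abs(null - mean)
    p_raw = (1.0 + (dev >= np.abs(obs - mean)).sum(axis=0)) / (n_perm + 1.0)
    p_raw = np.where(sd > 0, p_raw, np.nan)

    flat = p_raw.ravel()
    mask = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if mask.any():
        adj[mask] = bh_adjust(flat[mask])
    adj = adj.reshape(t, t)

    names = list(uniques)
    frame = lambda a: pd.DataFrame(a, index=names, columns=names)
    return EnrichmentResult(
        z=frame(z),
        pvalues=frame(p_raw),
        adj_pvalues=frame(adj),
        significant=frame(adj <= alpha),
        observed=frame(obs),
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard step-up with monotonicity enforcement; independent of input
    ordering.  Inputs must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
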