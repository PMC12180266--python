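"""Specificity metrics from vendor background probes.

Imaging ST kits include control probes with no complementary sequence in the
sample (false-positive probes, blank barcodes, unassigned codewords).  Their
calls estimate the false-discovery floor of the platform.  This module
implements the background-probe analyses:

* ranked whole-tissue counts and the set of targets whose signal falls within
  the background range;
* a global, segmentation-free FDR::

      FDR(%) = (background_calls / n_background_probes)
               * (n_target_genes / total_target_calls) * 100

  i.e. the mean per-background-probe call count expressed as a fraction of
  the mean per-target-gene call count;
* spatial statistics that rescue lowly abundant but genuinely localized
  signals: Moran's I of per-cell counts with inverse-distance weights (a
  technical false positive is spatially random, I ~ 0, while a true lowly
  expressed marker shows spatial structure, I > 0), and the median
  nearest-neighbor distance between calls of one probe (small when calls
  cluster inside scattered rare cells);
* a confidence classification combining both scales: within each Moran's-I
  stratum, a target whose total count is in the background range AND whose
  median NN distance is background-like (above the q-quantile of the
  background probes' NN distances) is flagged low-confidence;
* nuclear fraction and per-z-plane diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .io import ProbePanel, SegmentationMask, TranscriptTable

__all__ = [
    "FdrResult",
    "probe_count_ranking",
    "global_fdr",
    "morans_i",
    "morans_i_table",
    "scale_morans",
    "median_nn_distance",
    "classify_probe_confidence",
    "build_specificity_table",
    "nuclear_fraction",
    "z_histogram",
]


@dataclass(frozen=True)
class FdrResult:
    """Global segmentation-free FDR and its components."""

    background_barcode_calls: int
    number_of_background_barcodes: int
    number_of_target_genes: int
    total_target_gene_calls: int

    @property
    def fdr_percent(self) -> float:
        return (
            self.background_barcode_calls
            / self.number_of_background_barcodes
            * self.number_of_target_genes
            / self.total_target_gene_calls
            * 100.0
        )


def probe_count_ranking(tt: TranscriptTable, panel: ProbePanel) -> pd.DataFrame:
    """Whole-tissue call totals per probe, ranked, with background-range flag.

    Every panel probe appears (count 0 if never called).  Rank is by
    descending total count with ties broken by gene id.  A target is
    ``within_background_range`` iff its total does not exceed the largest
    background-probe total.
    """
    if not panel.background_genes:
        raise ValueError("panel has no background probes")
    counts = tt.df["gene"].value_counts()
    table = panel.entries[["gene_id", "kind"]].copy()
    table["total_count"] = (
        table["gene_id"].map(counts).fillna(0).astype(np.int64)
    )
    table = table.sort_values(
        ["total_count", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    bg_max = table.loc[table["kind"] == "background", "total_count"].max()
    table["within_background_range"] = table["total_count"] <= bg_max
    return table


def global_fdr(tt: TranscriptTable, panel: ProbePanel) -> FdrResult:
    """Evaluate the global FDR formula on raw whole-tissue call totals."""
    if not panel.background_genes:
        raise ValueError("panel has no background probes")
    counts = tt.df["gene"].value_counts()
    bg_calls = int(counts.reindex(panel.background_genes).fillna(0).sum())
    target_calls = int(counts.reindex(panel.target_genes).fillna(0).sum())
    if target_calls == 0:
        raise ValueError("no target gene calls; FDR undefined")
    return FdrResult(
        background_barcode_calls=bg_calls,
        number_of_background_barcodes=len(panel.background_genes),
        number_of_target_genes=len(panel.target_genes),
        total_target_gene_calls=target_calls,
    )


def _inverse_distance_weights(centroids: np.ndarray) -> np.ndarray:
    """Dense symmetric weight matrix w_ij = 1/d_ij, zero diagonal.

    Raises on coincident centroids, naming the offending pair.
    """
    d = pdist(centroids)
    if np.any(d == 0.0):
        w = squareform(d)
        i, j = np.argwhere((w == 0.0) & ~np.eye(len(w), dtype=bool))[0]
        raise ValueError(f"coincident centroids at indices {i} and {j}")
    return squareform(1.0 / d)


def morans_i(
    values: np.ndarray,
    centroids: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Global Moran's I with inverse-distance weights.

    ``w_ij = 1/d_ij`` (Euclidean distance between cell centroids in µm),
    ``w_ii = 0``, and no row standardization::

        I = n / sum(w) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    I ~ 0 for spatially random values, > 0 for clustered or gradient-like
    patterns, < 0 for checkerboard-like patterns; the permutation expectation
    is -1/(n-1).  A precomputed weight matrix can be supplied to amortize the
    O(n²) distance computation across probes.
    """
    x = np.asarray(values, dtype=float)
    pts = np.asarray(centroids, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("Moran's I needs at least 2 observations")
    if pts.shape[0] != n:
        raise ValueError("values and centroids must align")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("values have zero variance; Moran's I undefined")
    w = _inverse_distance_weights(pts) if weights is None else weights
    num = float(z @ (w @ z))
    return n / float(w.sum()) * num / denom


def morans_i_table(
    counts: pd.DataFrame, centroids: np.ndarray
) -> pd.Series:
    """Moran's I per column of a cell-by-gene count matrix.

    Computes the inverse-distance weight matrix once.  Columns with zero
    variance yield NaN (no spatial signal to measure).
    """
    w = _inverse_distance_weights(np.asarray(centroids, dtype=float))
    out = {}
    for gene in counts.columns:
        x = counts[gene].to_numpy(dtype=float)
        if x.std() == 0.0:
            out[gene] = np.nan
        else:
            out[gene] = morans_i(x, centroids, weights=w)
    return pd.Series(out, name="morans_i_raw")


def scale_morans(raw: pd.Series | np.ndarray) -> np.ndarray:
    """Min-max scale Moran's I values to [0, 1] across all probes jointly.

    The scaling population is all probes (targets and backgrounds) of one
    dataset, so both probe kinds share one axis.  NaNs pass through.
    """
    vals = np.asarray(raw, dtype=float)
    finite = vals[np.isfinite(vals)]
    if len(finite) < 2:
        raise ValueError("need at least 2 finite Moran's I values to scale")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        raise ValueError("all Moran's I values identical; scaling undefined")
    return (vals - lo) / (hi - lo)


def median_nn_distance(points: np.ndarray) -> float:
    """Median Euclidean nearest-neighbor distance of a point set (µm).

    Each point's nearest neighbor excludes itself; distances come from a
    kd-tree.  For a homogeneous Poisson process of intensity lambda the
    median is sqrt(ln 2 / (pi * lambda)) — the reference value for a
    spatially random probe.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points for NN distances")
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(np.median(d[:, 1]))


def classify_probe_confidence(
    table: pd.DataFrame,
    n_strata: int = 4,
    q: float = 0.95,
) -> pd.DataFrame:
    """Flag low-confidence targets by combining count, Moran's I and NN scale.

    Probes with valid Moran's I and NN distance are split into ``n_strata``
    equal-count strata by scaled Moran's I.  Within each stratum the NN
    threshold is the ``q``-quantile of the *background* probes' median NN
    distances (all probes of the stratum when it contains no background).  A
    target is ``low_confidence`` iff its median NN distance exceeds the
    threshold (background-like spatial randomness) AND its total count is
    within the background range.  Raising ``q`` can only raise thresholds,
    so the flag count is monotone non-increasing in ``q``.
    """
    required = {
        "gene_id",
        "kind",
        "morans_i_scaled",
        "median_nn_distance",
        "within_background_range",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"specificity table missing columns: {sorted(missing)}")
    out = table.copy()
    valid = (
        out["morans_i_scaled"].notna() & out["median_nn_distance"].notna()
    )
    if valid.sum() < n_strata:
        raise ValueError(
            f"need at least {n_strata} probes with valid Moran's I and NN "
            f"distance, got {int(valid.sum())}"
        )
    out["stratum"] = pd.array([pd.NA] * len(out), dtype="Int64")
    ranks = out.loc[valid, "morans_i_scaled"].rank(method="first")
    strata = np.ceil(ranks / len(ranks) * n_strata).astype(int) - 1
    out.loc[valid, "stratum"] = strata.astype(int)

    out["low_confidence"] = False
    for s in range(n_strata):
        in_s = valid & (out["stratum"] == s)
        if not in_s.any():
            continue
        bg = in_s & (out["kind"] == "background")
        pool = out.loc[bg if bg.any() else in_s, "median_nn_distance"]
        threshold = float(np.quantile(pool.to_numpy(dtype=float), q))
        flag = (
            in_s
            & (out["kind"] == "target")
            & (out["median_nn_distance"] > threshold)
            & out["within_background_range"]
        )
        out.loc[flag, "low_confidence"] = True
    return out


def build_specificity_table(
    tt: TranscriptTable,
    panel: ProbePanel,
    cell_counts: pd.DataFrame | None = None,
    centroids: np.ndarray | None = None,
    n_strata: int = 4,
    q: float = 0.95,
) -> pd.DataFrame:
    """Assemble the full per-probe specificity table.

    Combines whole-tissue count ranking, per-probe Moran's I of per-cell
    counts (when a cell-by-gene matrix with background columns and matching
    centroids is given), min-max scaled Moran's I, median NN distance of each
    probe's calls, and the stratified low-confidence classification.
    """
    table = probe_count_ranking(tt, panel)

    if cell_counts is not None and centroids is not None:
        mor = morans_i_table(cell_counts, centroids)
        table["morans_i_raw"] = table["gene_id"].map(mor)
    else:
        table["morans_i_raw"] = np.nan
    if table["morans_i_raw"].notna().sum() >= 2:
        table["morans_i_scaled"] = scale_morans(table["morans_i_raw"])
    else:
        table["morans_i_scaled"] = np.nan

    nn = {}
    for gene, grp in tt.df.groupby("gene", observed=True):
        if len(grp) >= 2:
            nn[gene] = median_nn_distance(grp[["x", "y"]].to_numpy())
    table["median_nn_distance"] = table["gene_id"].map(nn)

    try:
        table = classify_probe_confidence(table, n_strata=n_strata, q=q)
    except ValueError:
        table["stratum"] = pd.array([pd.NA] * len(table), dtype="Int64")
        table["low_confidence"] = False
    return table


def nuclear_fraction(
    tt: TranscriptTable,
    mask: SegmentationMask,
    per_probe: bool = False,
) -> float | pd.Series:
    """Fraction of calls landing on labeled (nuclear) mask pixels.

    Out-of-bounds positions count as outside.  Returns a single fraction, or
    a per-gene Series when ``per_probe``; empty inputs yield NaN.
    """
    s = mask.pixel_size
    h, w = mask.labels.shape
    xy = tt.coords
    if len(xy) == 0:
        return (
            pd.Series(dtype=float) if per_probe else float("nan")
        )
    col = np.floor(xy[:, 0] / s).astype(np.int64)
    row = np.floor(xy[:, 1] / s).astype(np.int64)
    inb = (col >= 0) & (col < w) & (row >= 0) & (row < h)
    inside = np.zeros(len(xy), dtype=bool)
    inside[inb] = mask.labels[row[inb], col[inb]] > 0
    if not per_probe:
        return float(inside.mean())
    return (
        pd.DataFrame({"gene": tt.df["gene"].to_numpy(), "inside": inside})
        .groupby("gene", observed=True)["inside"]
        .mean()
    )


def z_histogram(
    tt: TranscriptTable,
    planes: int,
    edge_fraction: float = 0.5,
) -> tuple[np.ndarray, bool]:
    """Per-plane call counts and a z-truncation flag.

    ``z`` must be interpretable as a plane index in ``[0, planes)``.  The
    distribution is flagged truncated when either edge plane holds more than
    ``edge_fraction`` of the modal plane's count — the signature of a stack
    that clips the axial extent of the sample (molecules above/below the
    imaged planes go undetected).
    """
    if planes < 1:
        raise ValueError("planes must be >= 1")
    z = tt.df["z"].to_numpy(dtype=float)
    zi = np.rint(z).astype(np.int64)
    if len(z) and not np.allclose(z, zi, atol=1e-6):
        raise ValueError("z values are not plane indices; supply a plane spacing")
    if len(z) and (zi.min() < 0 or zi.max() >= planes):
        raise ValueError("plane indices outside [0, planes)")
    counts = np.bincount(zi, minlength=planes) if len(z) else np.zeros(planes, int)
    mode = counts.max() if counts.size else 0
    truncated = bool(
        mode > 0
        and planes > 1
        and (
            counts[0] > edge_fraction * mode or counts[-1] > edge_fraction * mode
        )
    )
    return counts, truncated
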