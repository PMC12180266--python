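"""Sensitivity metrics: spatial binning, per-cell counts, cross-platform
correlation and detection-efficiency anchoring.

Sensitivity — the probability that a true transcript is detected — cannot be
read off a single platform's output.  Three complementary proxies are used:

* segmentation-free transcript/feature counts in square spatial bins whose
  area equals one Visium spot, which removes the confounding effect of cell
  segmentation when comparing platforms;
* median transcripts and features per segmented cell;
* per-gene mean counts per cell compared across platforms (Pearson r on log
  means), and anchored against a reference assay of known detection
  efficiency (snRNA-seq-style) to turn fold changes into absolute
  efficiencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io import CellByGeneMatrix, TranscriptTable

__all__ = [
    "BinGrid",
    "SensitivitySummary",
    "CoexpressionSimilarity",
    "visium_bin_side",
    "bin_counts",
    "per_cell_summary",
    "gene_mean_correlation",
    "estimate_detection_efficiency",
    "marker_coexpression_similarity",
]

#: pseudocount added to per-gene mean counts before the log10 transform used
#: for cross-platform correlation; stabilizes lowly expressed genes.
LOG_PSEUDOCOUNT = 0.01


@dataclass
class BinGrid:
    """Square-bin counts over the transcript bounding box.

    The grid is anchored at the bounding-box minimum and bins are half-open,
    so every in-extent transcript falls in exactly one bin.  Bins with zero
    transcripts inside the bounding box are retained.
    """

    origin: tuple[float, float]
    side: float
    shape: tuple[int, int]  # (ny, nx)
    totals: np.ndarray  # (ny, nx) transcript counts
    features: np.ndarray  # (ny, nx) number of genes with count > 0
    gene_counts: pd.DataFrame  # columns: bin_iy, bin_ix, gene, count

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 0

    def as_long(self) -> pd.DataFrame:
        """Long table (one row per bin) ready for ridge-style plotting."""
        iy, ix = np.indices(self.shape)
        return pd.DataFrame(
            {
                "bin_iy": iy.ravel(),
                "bin_ix": ix.ravel(),
                "transcripts": self.totals.ravel(),
                "features": self.features.ravel(),
            }
        )


@dataclass(frozen=True)
class SensitivitySummary:
    median_transcripts: float
    se_transcripts: float
    median_features: float
    se_features: float
    n_cells: int
    genes_used: tuple[str, ...]


def visium_bin_side(spot_diameter: float) -> float:
    """Side of the square whose area equals a circular spot of this diameter.

    For the standard 55 µm Visium spot this is (55/2)*sqrt(pi) = 48.74 µm,
    i.e. the square bin of area ~2375 µm² used for segmentation-free binning.
    """
    if spot_diameter < 0:
        raise ValueError("spot diameter must be non-negative")
    return spot_diameter / 2.0 * math.sqrt(math.pi)


def bin_counts(
    tt: TranscriptTable, side: float, genes: Sequence[str] | None = None
) -> BinGrid:
    """Count transcripts and features per square spatial bin."""
    if side <= 0:
        raise ValueError("bin side must be > 0")
    df = tt.df if genes is None else tt.df[tt.df["gene"].isin(set(genes))]
    if len(df) == 0:
        return BinGrid(
            origin=(0.0, 0.0),
            side=side,
            shape=(0, 0),
            totals=np.zeros((0, 0), dtype=np.int64),
            features=np.zeros((0, 0), dtype=np.int64),
            gene_counts=pd.DataFrame(columns=["bin_iy", "bin_ix", "gene", "count"]),
        )
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    x0, y0 = float(x.min()), float(y.min())
    ix = np.floor((x - x0) / side).astype(np.int64)
    iy = np.floor((y - y0) / side).astype(np.int64)
    nx, ny = int(ix.max()) + 1, int(iy.max()) + 1

    totals = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(totals, (iy, ix), 1)

    per_gene = (
        pd.DataFrame({"bin_iy": iy, "bin_ix": ix, "gene": df["gene"].to_numpy()})
        .groupby(["bin_iy", "bin_ix", "gene"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    features = np.zeros((ny, nx), dtype=np.int64)
    feat = per_gene.groupby(["bin_iy", "bin_ix"], observed=True).size()
    features[feat.index.get_level_values(0), feat.index.get_level_values(1)] = (
        feat.to_numpy()
    )
    return BinGrid(
        origin=(x0, y0),
        side=side,
        shape=(ny, nx),
        totals=totals,
        features=features,
        gene_counts=per_gene,
    )


def _bootstrap_se_median(
    values: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> float:
    """Standard error of the median via a seeded bootstrap."""
    if len(values) < 2:
        return 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    return float(np.median(values[idx], axis=1).std(ddof=1))


def per_cell_summary(
    m: CellByGeneMatrix,
    genes: Sequence[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> SensitivitySummary:
    """Median transcripts and features per cell (± bootstrap standard error).

    Features are genes with strictly positive count in a cell.  The gene
    subset defaults to all matrix columns (pass the shared panel to compare
    platforms on common genes).
    """
    if m.n_cells == 0:
        raise ValueError("matrix has no cells")
    cols = m.genes if genes is None else [g for g in genes if g in m.counts.columns]
    sub = m.counts[cols] if cols else m.counts.iloc[:, :0]
    transcripts = sub.sum(axis=1).to_numpy(dtype=float)
    features = (sub > 0).sum(axis=1).to_numpy(dtype=float)
    return SensitivitySummary(
        median_transcripts=float(np.median(transcripts)),
        se_transcripts=_bootstrap_se_median(transcripts, n_boot, seed),
        median_features=float(np.median(features)),
        se_features=_bootstrap_se_median(features, n_boot, seed + 1),
        n_cells=m.n_cells,
        genes_used=tuple(cols),
    )


def gene_mean_correlation(
    m_a: CellByGeneMatrix,
    m_b: CellByGeneMatrix,
    genes: Sequence[str] | None = None,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of per-gene mean counts per cell between platforms.

    Means are compared on the log10(mean + pseudocount) scale.  Returns the
    coefficient and a per-gene table of the raw means for plotting against
    the identity line (equal detected transcripts in both platforms).
    """
    shared = [g for g in (genes or m_a.genes) if g in m_a.counts and g in m_b.counts]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    mean_a = m_a.counts[shared].mean(axis=0)
    mean_b = m_b.counts[shared].mean(axis=0)
    la = np.log10(mean_a.to_numpy() + pseudocount)
    lb = np.log10(mean_b.to_numpy() + pseudocount)
    if np.isclose(la.std(), 0.0) or np.isclose(lb.std(), 0.0):
        raise ValueError("zero variance in log gene means; correlation undefined")
    r = float(sstats.pearsonr(la, lb).statistic)
    table = pd.DataFrame(
        {"gene": shared, "mean_a": mean_a.to_numpy(), "mean_b": mean_b.to_numpy()}
    )
    return r, table


def estimate_detection_efficiency(
    fold_low: float,
    fold_high: float,
    ref_eff_low: float,
    ref_eff_high: float,
) -> tuple[float, float]:
    """Anchor iST detection efficiency to a reference assay.

    Given the fold range by which iST per-cell mean counts exceed the
    reference and the reference's known efficiency range, the iST efficiency
    interval is the product of the two ranges, clipped to 1.  E.g. 2.3–2.5x
    the counts of a 14–15% efficient snRNA-seq chemistry gives ~32–37%.
    """
    if fold_low <= 0 or fold_high <= 0 or fold_low > fold_high:
        raise ValueError("fold range must be positive with low <= high")
    if not (0 < ref_eff_low <= ref_eff_high <= 1):
        raise ValueError("reference efficiency range must lie in (0, 1]")
    return (
        min(1.0, fold_low * ref_eff_low),
        min(1.0, fold_high * ref_eff_high),
    )


@dataclass
class CoexpressionSimilarity:
    """Similarity of marker co-expression structure between two matrices.

    ``corr_a``/``corr_b`` are pairwise Pearson correlations of marker counts
    across cells.  ``r`` is the (signed) Pearson correlation between the two
    upper-triangle vectors; ``r_squared`` its square (the R² reported when
    comparing a platform's co-expression pattern to a reference).
    """

    corr_a: pd.DataFrame
    corr_b: pd.DataFrame
    r: float
    markers_used: tuple[str, ...]

    @property
    def r_squared(self) -> float:
        return self.r**2


def marker_coexpression_similarity(
    m_a: CellByGeneMatrix, m_b: CellByGeneMatrix, markers: Sequence[str]
) -> CoexpressionSimilarity:
    """Compare pairwise marker-correlation structure between two datasets."""
    usable = []
    for g in markers:
        if g not in m_a.counts.columns or g not in m_b.counts.columns:
            warnings.warn(f"marker {g!r} missing from a matrix; excluded")
            continue
        if m_a.counts[g].std() == 0 or m_b.counts[g].std() == 0:
            warnings.warn(f"marker {g!r} has zero variance; excluded")
            continue
        usable.append(g)
    if len(usable) < 2:
        raise ValueError("need at least 2 usable markers with nonzero variance")
    corr_a = m_a.counts[usable].corr(method="pearson")
    corr_b = m_b.counts[usable].corr(method="pearson")
    iu = np.triu_indices(len(usable), k=1)
    va = corr_a.to_numpy()[iu]
    vb = corr_b.to_numpy()[iu]
    if len(va) < 2 or np.isclose(va.std(), 0) or np.isclose(vb.std(), 0):
        raise ValueError("fewer than 2 usable marker pairs with variance")
    r = float(sstats.pearsonr(va, vb).statistic)
    return CoexpressionSimilarity(corr_a, corr_b, r, tuple(usable))
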