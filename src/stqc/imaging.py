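"""Optical QC metrics and stitch-border transcript deduplication.

Resolution is measured on sub-resolution fluorescent beads: detect beads as
local intensity maxima, pull 1-D profiles through each peak along x, y and z,
and report the median full width at half maximum (FWHM) per axis with its
median absolute deviation (MAD).  Spot quality is measured on 21-sample line
profiles through called transcript spots: after subtracting the darkest
pixel of the image, SNR = (I(0) - mu_bg) / sigma_bg and SBR = I(0) / mu_bg,
with the 10 outermost samples (|x| > 5) as the background annulus.

Stitch-border deduplication removes the duplicate transcripts that tile
stitching inaccuracies create along tile-grid lines: same-gene call pairs
straddling a grid line with a consistent offset (the consensus stitching
shift) are collapsed, keeping the copy nearer the line.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import TranscriptTable
from .simulate import BeadStack, LineProfile

__all__ = [
    "ResolutionSummary",
    "detect_local_maxima",
    "fwhm",
    "mad",
    "bead_resolution_summary",
    "snr",
    "sbr",
    "dedup_stitch",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = 2.355 sigma


@dataclass(frozen=True)
class ResolutionSummary:
    """Median FWHM (nm) per axis and MAD over beads.

    ``fwhm_inplane_nm`` pools the x and y measurements of all beads and
    reports their joint median, the single in-plane resolution figure.
    """

    fwhm_nm: dict  # axis ("x"|"y"|"z") -> median FWHM
    mad_nm: dict  # axis -> MAD
    fwhm_inplane_nm: float
    mad_inplane_nm: float
    n_beads: int


def detect_local_maxima(
    image: np.ndarray, threshold: float, min_distance: int = 1
) -> np.ndarray:
    """Coordinates of strict local maxima above a threshold.

    A voxel is a candidate when its intensity strictly exceeds every
    neighbor (full connectivity) and exceeds ``threshold``.  Candidates
    closer than ``min_distance`` (Euclidean) are suppressed keeping the
    brighter one, ties broken by lexicographic coordinate.  Returns an
    (n, ndim) integer array, possibly empty.
    """
    img = np.asarray(image, dtype=float)
    footprint = np.ones((3,) * img.ndim, dtype=bool)
    footprint[(1,) * img.ndim] = False
    neigh_max = ndimage.maximum_filter(img, footprint=footprint, mode="constant", cval=-np.inf)
    cand = np.argwhere((img > neigh_max) & (img > threshold))
    if len(cand) == 0:
        return cand.reshape(0, img.ndim)
    inten = img[tuple(cand.T)]
    # brighter first; ties by lexicographic coordinate
    order = np.lexsort(tuple(cand.T[::-1]) + (-inten,))
    cand = cand[order]
    kept: list[np.ndarray] = []
    for c in cand:
        if all(np.sum((c - k) ** 2) >= min_distance**2 for k in kept):
            kept.append(c)
    return np.array(kept, dtype=np.int64).reshape(len(kept), img.ndim)


def fwhm(profile: np.ndarray, spacing: float = 1.0) -> float:
    """Full width at half maximum of a 1-D peak, in ``spacing`` units.

    The baseline is the smaller of the two profile end samples and the peak
    is the (unique, interior) maximum sample; the two half-maximum crossings
    are located by linear interpolation between samples.  Invariant to
    positive affine intensity transforms a*I + b.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    k = int(np.argmax(p))
    if k == 0 or k == len(p) - 1:
        raise ValueError("profile maximum at an edge; no interior peak")
    baseline = min(p[0], p[-1])
    height = p[k] - baseline
    if height <= 0:
        raise ValueError("flat or inverted profile; no peak above baseline")
    half = baseline + height / 2.0

    def _cross(idx_range) -> float:
        prev = k
        for i in idx_range:
            if p[i] < half:
                # linear interpolation between samples i and prev
                t = (half - p[i]) / (p[prev] - p[i])
                return i + t * (prev - i)
            prev = i
        raise ValueError("peak plateau wider than profile; FWHM undefined")

    left = _cross(range(k - 1, -1, -1))
    right = _cross(range(k + 1, len(p)))
    return (right - left) * spacing


def mad(values: np.ndarray) -> float:
    """Median absolute deviation: median(|X_i - median(X)|)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("MAD of empty input")
    return float(np.median(np.abs(v - np.median(v))))


def bead_resolution_summary(
    stack: BeadStack, threshold: float, min_distance: int = 5
) -> ResolutionSummary:
    """Bead-based resolution: median ± MAD of per-axis FWHM over beads.

    Beads are detected as local maxima in the 3-D stack; for each bead the
    raw pixel rows through the peak along x, y and z are extracted (no
    sub-pixel refinement) and their FWHM converted to nm via the voxel size.
    """
    peaks = detect_local_maxima(stack.data, threshold, min_distance)
    if len(peaks) == 0:
        raise ValueError("no beads detected above threshold")
    vz, vy, vx = stack.voxel_size
    per_axis: dict[str, list[float]] = {"x": [], "y": [], "z": []}
    for z, y, x in peaks:
        profiles = {
            "z": (stack.data[:, y, x], vz),
            "y": (stack.data[z, :, x], vy),
            "x": (stack.data[z, y, :], vx),
        }
        try:
            widths = {
                ax: fwhm(prof, spacing) * 1000.0  # µm -> nm
                for ax, (prof, spacing) in profiles.items()
            }
        except ValueError:
            continue  # bead too close to a stack face for a clean profile
        # only beads with all three axes measurable contribute
        for ax, wd in widths.items():
            per_axis[ax].append(wd)
    if not per_axis["x"]:
        raise ValueError("no bead yielded measurable profiles on all axes")
    inplane = np.array(per_axis["x"] + per_axis["y"])
    return ResolutionSummary(
        fwhm_nm={ax: float(np.median(v)) for ax, v in per_axis.items()},
        mad_nm={ax: mad(np.array(v)) for ax, v in per_axis.items()},
        fwhm_inplane_nm=float(np.median(inplane)),
        mad_inplane_nm=mad(inplane),
        n_beads=len(per_axis["x"]),
    )


_BG = np.abs(np.arange(-10, 11)) > 5  # the 10 outermost samples


def snr(p: LineProfile) -> float:
    """Signal-to-noise ratio of a dark-subtracted spot profile."""
    i = p.samples - p.i_dark
    bg = i[_BG]
    sigma = float(bg.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("constant background; SNR undefined (sigma_bg = 0)")
    return float((i[10] - bg.mean()) / sigma)


def sbr(p: LineProfile) -> float:
    """Signal-to-background ratio of a dark-subtracted spot profile."""
    i = p.samples - p.i_dark
    mu = float(i[_BG].mean())
    if mu <= 0.0:
        raise ValueError("non-positive background mean; SBR undefined")
    return float(i[10] / mu)


# ---------------------------------------------------------------------------
# stitch deduplication


def _lines_in(lo: float, hi: float, tile_size: float) -> list[float]:
    k0 = int(math.floor(lo / tile_size)) + 1
    k1 = int(math.ceil(hi / tile_size)) - 1
    return [k * tile_size for k in range(k0, k1 + 1) if lo < k * tile_size < hi]


def dedup_stitch(
    tt: TranscriptTable,
    tile_size: float = 2144.0,
    window: float = 30.0,
    max_copies: int = 400,
    min_occurrences: int = 10,
    tolerance: float = 0.5,
    z_tolerance: float = 1.0,
    min_consensus_votes: int = 3,
) -> tuple[TranscriptTable, float]:
    """Remove stitch-border duplicate transcripts along a tile grid.

    For every interior grid line (multiples of ``tile_size`` in x and y
    within the data extent), same-gene call pairs straddling the line with
    both members within ``window`` of it are candidate duplicates, drawn
    from genes with fewer than ``max_copies`` calls in the window.  The
    consensus stitching shift for the line is estimated from the pair
    offsets of genes occurring at least ``min_occurrences`` times in the
    window: offsets are binned to 1-unit resolution, the modal bin (if it
    holds at least ``min_consensus_votes`` pairs) wins, and the consensus is
    refined to the component-wise median of the offsets in that bin.  Pairs
    matching the consensus within ``tolerance`` per axis (and
    ``z_tolerance`` in z) are then greedily collapsed in order of offset
    error, removing the member farther from the line.

    Returns the deduplicated table and ``duplicate_rate`` =
    removed / total.  Coordinates, units and the tile grid must agree (the
    defaults are the Molecular Cartography pixel-grid parameters: 2144-pixel
    tiles, 30-pixel window, shift from genes with < 400 copies occurring
    >= 10 times).
    """
    if window >= tile_size / 2:
        raise ValueError("window must be smaller than half the tile size")
    df = tt.df
    n_total = len(df)
    if n_total == 0:
        return TranscriptTable(df.copy(), panel=tt.panel), 0.0
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    z = df["z"].to_numpy()
    genes = df["gene"].to_numpy()

    lines = [("x", line) for line in _lines_in(x.min(), x.max(), tile_size)] + [
        ("y", line) for line in _lines_in(y.min(), y.max(), tile_size)
    ]
    if not lines:
        return TranscriptTable(df.copy(), panel=tt.panel), 0.0

    removed: set[int] = set()  # positional indices into df
    alive = np.ones(n_total, dtype=bool)
    for axis, line in lines:
        c = x if axis == "x" else y
        alive[list(removed)] = False
        near = np.where((np.abs(c - line) <= window) & alive)[0]
        if len(near) == 0:
            continue
        low = near[c[near] < line]
        high = near[c[near] >= line]
        if len(low) == 0 or len(high) == 0:
            continue
        window_counts = Counter(genes[near])

        # enumerate candidate pairs per gene
        cand: list[tuple[float, int, int, float, float, float]] = []
        by_gene_high: dict[str, np.ndarray] = {}
        for g in np.unique(genes[low]):
            if window_counts[g] >= max_copies:
                continue
            hi_g = by_gene_high.setdefault(g, high[genes[high] == g])
            if len(hi_g) == 0:
                continue
            for i in low[genes[low] == g]:
                for j in hi_g:
                    dz = z[j] - z[i]
                    if abs(dz) > z_tolerance:
                        continue
                    cand.append(
                        (window_counts[g], i, j, x[j] - x[i], y[j] - y[i], dz)
                    )
        if not cand:
            continue

        # consensus from well-populated genes
        votes = Counter(
            (round(dx), round(dy))
            for occ, _i, _j, dx, dy, _dz in cand
            if occ >= min_occurrences
        )
        if not votes:
            continue
        (bx, by), n_votes = votes.most_common(1)[0]
        if n_votes < min_consensus_votes:
            continue
        in_bin = [
            (dx, dy)
            for occ, _i, _j, dx, dy, _dz in cand
            if occ >= min_occurrences and round(dx) == bx and round(dy) == by
        ]
        cons_dx = float(np.median([d[0] for d in in_bin]))
        cons_dy = float(np.median([d[1] for d in in_bin]))

        # greedy one-to-one matching by offset error
        matches = []
        for _occ, i, j, dx, dy, _dz in cand:
            err = max(abs(dx - cons_dx), abs(dy - cons_dy))
            if abs(dx - cons_dx) <= tolerance and abs(dy - cons_dy) <= tolerance:
                matches.append((err, i, j))
        matches.sort(key=lambda t: (t[0], t[1], t[2]))
        used: set[int] = set()
        for err, i, j in matches:
            if i in used or j in used or i in removed or j in removed:
                continue
            used.update((i, j))
            # drop the member farther from the line (tie: the later record)
            di, dj = abs(c[i] - line), abs(c[j] - line)
            removed.add(i if (di > dj or (di == dj and i > j)) else j)

    keep = np.ones(n_total, dtype=bool)
    keep[list(removed)] = False
    out = TranscriptTable(df[keep].reset_index(drop=True), panel=tt.panel)
    return out, len(removed) / n_total
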