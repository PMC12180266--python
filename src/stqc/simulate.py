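"""Synthetic iST data with known ground truth.

The tissue generator emulates the microanatomy that makes medulloblastoma
with extensive nodularity (MBEN) a useful QC benchmark: round nodules of
post-mitotic, neuronally differentiated tumor cells embedded in an
internodular compartment of proliferating precursor-like and stromal cells.
Each simulated cell carries a type with a marker panel of per-gene mean true
copy numbers; detection is Poisson thinning with a global efficiency
``epsilon``, so detected counts per cell are Poisson(epsilon * lambda_g).
Background-probe calls follow a homogeneous spatial Poisson process — the
null model under which a purely technical false-positive signal is randomly
distributed in the tissue.

Also provided: planted stitch-border duplicates on a tile grid, 3-D bead
stacks with known FWHM, and spot line profiles with known SNR/SBR, each
returning a ``SimTruth`` describing exactly what was planted.

All generators take an explicit seed and derive one independent child stream
per component (cell placement, counts, positions, background, ...), so every
layer is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ProbePanel, SegmentationMask, TranscriptTable

__all__ = [
    "CellTypeSpec",
    "TissueSimConfig",
    "SimTruth",
    "BeadStack",
    "LineProfile",
    "simulate_tissue",
    "plant_stitch_duplicates",
    "simulate_bead_stack",
    "simulate_spot_profiles",
]


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type.

    ``markers`` maps gene id to the mean number of *true* transcript copies
    per cell (lambda_g).  ``proportion`` is the sampling weight within the
    type's compartment ("nodular" or "internodular").
    """

    name: str
    compartment: str
    proportion: float
    markers: Mapping[str, float]


def _default_cell_types() -> tuple[CellTypeSpec, ...]:
    # Two-compartment MBEN-like panel: nodular differentiated-neuronal cells
    # (NRXN3/RBFOX3-style markers) vs internodular precursor-like and stromal
    # cells (LAMA2/GLI1/MKI67-style markers).
    return (
        CellTypeSpec(
            "neuronal_diff",
            "nodular",
            0.8,
            {"NRXN3": 60.0, "RBFOX3": 40.0, "CNTN2": 20.0},
        ),
        CellTypeSpec(
            "astrocytic", "nodular", 0.2, {"GFAP": 50.0, "AQP4": 25.0}
        ),
        CellTypeSpec(
            "cgnp",
            "internodular",
            0.7,
            {"LAMA2": 50.0, "GLI1": 30.0, "MKI67": 35.0},
        ),
        CellTypeSpec(
            "stromal", "internodular", 0.3, {"COL1A1": 45.0, "PTCH1": 15.0}
        ),
    )


@dataclass
class TissueSimConfig:
    """Study conditions for the two-compartment tissue simulation.

    Defaults approximate a 1 mm² MBEN field: ~1500 nuclei/mm² (dense
    pediatric tumor tissue), nodules of 100–200 µm radius, 4 µm nucleus
    radius, detection efficiency 0.35 (the anchored iST estimate of ~33–37%),
    and background probes at a few hundred calls/mm² so that their counts
    bracket lowly expressed targets.
    """

    field_size: tuple[float, float] = (1000.0, 1000.0)  # (width, height) µm
    cell_density: float = 1500.0  # cells / mm²
    nodules: Sequence[tuple[float, float, float]] = (
        (300.0, 300.0, 180.0),
        (700.0, 650.0, 160.0),
        (250.0, 750.0, 120.0),
    )
    cell_types: Sequence[CellTypeSpec] = field(default_factory=_default_cell_types)
    detection_efficiency: float = 0.35
    background_rates: Mapping[str, float] = field(
        default_factory=lambda: {f"Blank-{i:02d}": 150.0 + 25.0 * i for i in range(8)}
    )
    #: target genes simulated with *no* spatial structure (uniform calls/mm²);
    #: used to plant pseudo-targets that behave like background probes.
    uniform_target_rates: Mapping[str, float] = field(default_factory=dict)
    nucleus_radius: float = 4.0  # µm
    pixel_size: float = 1.0  # µm/pixel of the rendered mask
    z_range: float = 10.0  # µm; z coordinates are uniform in [0, z_range)
    background_class: str = "blank"

    def validate(self) -> None:
        if not 0.0 <= self.detection_efficiency <= 1.0:
            raise ValueError("detection_efficiency must be in [0, 1]")
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")
        if any(r < 0 for r in self.background_rates.values()):
            raise ValueError("background rates must be >= 0")
        w, h = self.field_size
        for cx, cy, r in self.nodules:
            if not (0 <= cx <= w and 0 <= cy <= h):
                raise ValueError(f"nodule center ({cx}, {cy}) outside field")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    cells: pd.DataFrame | None = None  # cell, x, y, type, compartment
    expected_counts: pd.Series | None = None  # gene -> expected detected total
    expected_per_cell: pd.DataFrame | None = None  # type x gene, eps*lambda
    duplicate_pairs: pd.DataFrame | None = None  # original_id, duplicate_id
    bead_centers: np.ndarray | None = None  # (n, 3) voxel indices (z, y, x)
    fwhm_um: tuple[float, float, float] | None = None  # (z, y, x)
    snr: float | None = None
    sbr: float | None = None


@dataclass
class BeadStack:
    """3-D intensity array (z, y, x) with voxel sizes in µm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]  # (z, y, x) µm

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("bead stack must be 3-D (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")


@dataclass
class LineProfile:
    """21 intensity samples through a spot center (index -10..+10 in x).

    ``i_dark`` is the darkest pixel of the source image and is subtracted
    from all raw intensities before SNR/SBR evaluation.
    """

    samples: np.ndarray
    i_dark: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (21,):
            raise ValueError("line profile must have exactly 21 samples")
        if self.i_dark > self.samples.min() + 1e-9:
            raise ValueError("i_dark must not exceed the darkest profile sample")


# ---------------------------------------------------------------------------
# tissue


def _hard_core_points(
    rng: np.random.Generator,
    n: int,
    field: tuple[float, float],
    min_dist: float,
    max_tries_per_point: int = 200,
) -> np.ndarray:
    """Dart-throwing hard-core process on a spatial hash grid."""
    w, h = field
    margin = min_dist / 2.0
    cell = max(min_dist, 1e-9)
    nx = max(1, int(math.ceil(w / cell)))
    ny = max(1, int(math.ceil(h / cell)))
    grid: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries_per_point * max(n, 1)
    while len(pts) < n:
        if tries >= budget:
            raise RuntimeError(
                f"hard-core packing failed: placed {len(pts)}/{n} points "
                f"(density infeasible for min distance {min_dist} µm)"
            )
        tries += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        gx, gy = int(x / cell), int(y / cell)
        ok = True
        for ix in range(gx - 1, gx + 2):
            for iy in range(gy - 1, gy + 2):
                for j in grid.get((ix, iy), ()):
                    px, py = pts[j]
                    if (px - x) ** 2 + (py - y) ** 2 < min_dist**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gx, gy), []).append(len(pts))
            pts.append((x, y))
    return np.asarray(pts, dtype=float).reshape(n, 2)


def _render_disc_mask(
    centers: np.ndarray, radius: float, field: tuple[float, float], pixel_size: float
) -> SegmentationMask:
    w, h = field
    nx = int(round(w / pixel_size))
    ny = int(round(h / pixel_size))
    labels = np.zeros((ny, nx), dtype=np.int32)
    r_px = radius / pixel_size
    for i, (cx, cy) in enumerate(centers, start=1):
        cxp, cyp = cx / pixel_size, cy / pixel_size
        x0 = max(0, int(cxp - r_px - 1))
        x1 = min(nx, int(cxp + r_px + 2))
        y0 = max(0, int(cyp - r_px - 1))
        y1 = min(ny, int(cyp + r_px + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        # pixel centers at index + 0.5
        inside = (xx + 0.5 - cxp) ** 2 + (yy + 0.5 - cyp) ** 2 <= r_px**2
        labels[y0:y1, x0:x1][inside] = i
    return SegmentationMask(labels, pixel_size)


def simulate_tissue(
    cfg: TissueSimConfig, seed: int | None = 0
) -> tuple[TranscriptTable, SegmentationMask, ProbePanel, SimTruth]:
    """Simulate a two-compartment tissue with known detection ground truth.

    Cells are placed by a hard-core point process (minimum separation twice
    the nucleus radius, so rendered nuclei never touch), typed by compartment
    membership, and emit per-gene detected counts ~ Poisson(eps * lambda_g)
    at positions uniform in the nuclear disc.  Background probes (and any
    configured uniform pseudo-targets) are homogeneous Poisson processes over
    the field.  Deterministic under a fixed seed.
    """
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    rng_cells, rng_types, rng_counts, rng_pos, rng_bg = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    w, h = cfg.field_size
    area_mm2 = w * h / 1e6
    n_cells = int(round(cfg.cell_density * area_mm2))
    centers = _hard_core_points(
        rng_cells, n_cells, cfg.field_size, min_dist=2.0 * cfg.nucleus_radius
    )

    nod = np.zeros(n_cells, dtype=bool)
    for cx, cy, r in cfg.nodules:
        nod |= (centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2 <= r**2

    types = np.empty(n_cells, dtype=object)
    for compartment, inside in (("nodular", nod), ("internodular", ~nod)):
        specs = [t for t in cfg.cell_types if t.compartment == compartment]
        idx = np.where(inside)[0]
        if not len(idx):
            continue
        if not specs:
            raise ValueError(f"no cell types declared for {compartment} compartment")
        p = np.array([t.proportion for t in specs], dtype=float)
        p /= p.sum()
        choice = rng_types.choice(len(specs), size=len(idx), p=p)
        types[idx] = np.array([t.name for t in specs], dtype=object)[choice]

    by_name = {t.name: t for t in cfg.cell_types}
    marker_genes = sorted({g for t in cfg.cell_types for g in t.markers})
    eps = cfg.detection_efficiency

    genes_out: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    # detected counts per cell per marker gene
    for gene in marker_genes:
        lam = np.array([by_name[t].markers.get(gene, 0.0) for t in types])
        counts = rng_counts.poisson(eps * lam)
        total = int(counts.sum())
        if total == 0:
            continue
        owner = np.repeat(np.arange(n_cells), counts)
        rr = cfg.nucleus_radius * np.sqrt(rng_pos.uniform(size=total))
        th = rng_pos.uniform(0.0, 2.0 * math.pi, size=total)
        xs.append(centers[owner, 0] + rr * np.cos(th))
        ys.append(centers[owner, 1] + rr * np.sin(th))
        genes_out.append(np.full(total, gene, dtype=object))

    def _uniform_calls(rates: Mapping[str, float], rng: np.random.Generator) -> None:
        for gene, rate in rates.items():
            n = rng.poisson(rate * area_mm2)
            if n == 0:
                continue
            xs.append(rng.uniform(0.0, w, size=n))
            ys.append(rng.uniform(0.0, h, size=n))
            genes_out.append(np.full(n, gene, dtype=object))

    _uniform_calls(dict(cfg.background_rates), rng_bg)
    _uniform_calls(dict(cfg.uniform_target_rates), rng_bg)

    if xs:
        gene = np.concatenate(genes_out)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
    else:
        gene, x, y = np.empty(0, object), np.empty(0), np.empty(0)
    z = rng_bg.uniform(0.0, cfg.z_range, size=len(x))

    panel = ProbePanel.from_genes(
        targets=marker_genes + sorted(cfg.uniform_target_rates),
        backgrounds=sorted(cfg.background_rates),
        background_class=cfg.background_class,
    )
    tt = TranscriptTable.from_arrays(gene, x, y, z=z, panel=panel)
    mask = _render_disc_mask(centers, cfg.nucleus_radius, cfg.field_size, cfg.pixel_size)

    cells_df = pd.DataFrame(
        {
            "cell": np.arange(1, n_cells + 1),
            "x": centers[:, 0],
            "y": centers[:, 1],
            "type": types,
            "compartment": np.where(nod, "nodular", "internodular"),
        }
    )
    exp_per_cell = pd.DataFrame(
        {
            g: {t.name: eps * t.markers.get(g, 0.0) for t in cfg.cell_types}
            for g in marker_genes
        }
    )
    type_counts = cells_df["type"].value_counts()
    expected = pd.Series(
        {
            g: float(
                sum(
                    type_counts.get(t.name, 0) * eps * t.markers.get(g, 0.0)
                    for t in cfg.cell_types
                )
            )
            for g in marker_genes
        }
    )
    truth = SimTruth(
        cells=cells_df, expected_counts=expected, expected_per_cell=exp_per_cell
    )
    return tt, mask, panel, truth


# ---------------------------------------------------------------------------
# stitch duplicates


def _grid_lines(lo: float, hi: float, tile_size: float) -> np.ndarray:
    """Interior tile-grid lines (multiples of tile_size) within (lo, hi)."""
    k0 = int(math.floor(lo / tile_size)) + 1
    k1 = int(math.ceil(hi / tile_size)) - 1
    return np.array([k * tile_size for k in range(k0, k1 + 1) if lo < k * tile_size < hi])


def plant_stitch_duplicates(
    tt: TranscriptTable,
    rate: float,
    shift: tuple[float, float],
    tile_size: float,
    seed: int | None = None,
) -> tuple[TranscriptTable, SimTruth]:
    """Plant stitch-border duplicates for a fraction of transcripts.

    Emulates the artifact where a molecule near a tile border is recorded in
    both adjacent tiles with a consistent offset.  ``round(rate * n)`` records
    nearest to the tile-grid lines are copied across their nearest line with
    the given (dx, dy) shift, oriented so that for a vertical line the
    low-side -> high-side offset is exactly ``shift`` (and symmetrically in y
    for horizontal lines).  Only records closer to the line than the
    crossing-axis shift component are eligible, so every planted copy truly
    lands on the far side; an error is raised if too few records qualify.

    The returned truth lists (original record_id, duplicate record_id) pairs.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    n = len(tt)
    n_plant = int(round(rate * n))
    df = tt.df
    if n_plant == 0:
        return TranscriptTable(df.copy(), panel=tt.panel), SimTruth(
            duplicate_pairs=pd.DataFrame(columns=["original_id", "duplicate_id"])
        )
    dx, dy = float(shift[0]), float(shift[1])
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    vx = _grid_lines(x.min(), x.max(), tile_size)
    vy = _grid_lines(y.min(), y.max(), tile_size)
    if len(vx) == 0 and len(vy) == 0:
        raise ValueError("no tile-grid lines within the transcript extent")

    big = np.inf
    dist_v = (
        np.abs(x[:, None] - vx[None, :]).min(axis=1) if len(vx) else np.full(n, big)
    )
    dist_h = (
        np.abs(y[:, None] - vy[None, :]).min(axis=1) if len(vy) else np.full(n, big)
    )
    use_v = dist_v <= dist_h
    dist = np.where(use_v, dist_v, dist_h)
    # eligibility: the copy must cross the line
    axis_shift = np.where(use_v, abs(dx), abs(dy))
    eligible = np.where(dist < axis_shift)[0]
    if len(eligible) < n_plant:
        raise ValueError(
            f"only {len(eligible)} records lie within the shift distance of a "
            f"grid line; cannot plant {n_plant} duplicates"
        )
    order = eligible[np.argsort(dist[eligible], kind="stable")][:n_plant]

    new_rows = []
    next_id = int(df["record_id"].max()) + 1
    pairs = []
    for idx in order:
        row = df.iloc[idx]
        if use_v[idx]:
            line = vx[np.argmin(np.abs(x[idx] - vx))]
            sgn = 1.0 if x[idx] < line else -1.0
        else:
            line = vy[np.argmin(np.abs(y[idx] - vy))]
            sgn = 1.0 if y[idx] < line else -1.0
        new_rows.append(
            {
                "gene": row["gene"],
                "x": row["x"] + sgn * abs(dx) if use_v[idx] else row["x"] + sgn * dx,
                "y": row["y"] + sgn * dy if use_v[idx] else row["y"] + sgn * abs(dy),
                "z": row["z"],
                "tile_id": row["tile_id"],
                "record_id": next_id,
            }
        )
        pairs.append({"original_id": int(row["record_id"]), "duplicate_id": next_id})
        next_id += 1

    out = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    out["tile_id"] = out["tile_id"].astype("Int64")
    truth = SimTruth(duplicate_pairs=pd.DataFrame(pairs))
    return TranscriptTable(out, panel=tt.panel), truth


# ---------------------------------------------------------------------------
# optics


def simulate_bead_stack(
    fwhm_xyz: tuple[float, float, float],
    voxel: tuple[float, float, float],
    n_beads: int,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    amplitude: float = 1000.0,
    shape: tuple[int, int, int] | None = None,
    snap_to_voxel: bool = True,
    fwhm_jitter: float = 0.0,
) -> tuple[BeadStack, SimTruth]:
    """Render sub-resolution beads as 3-D Gaussians plus Gaussian noise.

    ``fwhm_xyz`` and ``voxel`` are (x, y, z) µm.  Beads are placed at random
    non-overlapping positions; by default centers snap to voxel centers
    because the downstream profile extraction reads raw pixel rows through
    the detected maximum without sub-pixel refinement (an off-center peak
    sample would bias the half-max level).  ``fwhm_jitter`` multiplies each
    bead's FWHM by ``1 + jitter*u`` with u uniform in [-1, 1].

    Truth stores bead centers (z, y, x voxel indices) and the nominal FWHM.
    """
    fx, fy, fz = fwhm_xyz
    vx, vy, vz = voxel
    if min(fx, fy, fz) <= 0 or min(vx, vy, vz) <= 0:
        raise ValueError("FWHM and voxel sizes must be positive")
    rng = np.random.default_rng(seed)
    sig = np.array([fz / vz, fy / vy, fx / vx]) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = np.ceil(4.0 * sig + 1).astype(int)  # rendering half-extent, voxels
    if shape is None:
        per = 2 * half + 2
        m = max(1, int(math.ceil(n_beads ** (1.0 / 3.0))))
        shape = tuple(int(d) for d in (per * (m + 2)))  # type: ignore[assignment]
    shape = tuple(shape)
    data = np.zeros(shape, dtype=float)

    centers = []
    min_sep = 2.0 * np.max(half)
    tries = 0
    while len(centers) < n_beads:
        if tries > 500 * max(n_beads, 1):
            raise RuntimeError("could not place beads without overlap")
        tries += 1
        c = np.array(
            [rng.uniform(half[d] + 1, shape[d] - half[d] - 2) for d in range(3)]
        )
        if snap_to_voxel:
            c = np.round(c)
        if any(np.max(np.abs(c - p)) < min_sep for p in centers):
            continue
        centers.append(c)
    centers_arr = np.array(centers).reshape(len(centers), 3)

    for c in centers_arr:
        s = sig * (1.0 + fwhm_jitter * rng.uniform(-1.0, 1.0)) if fwhm_jitter else sig
        lo = np.maximum(0, np.floor(c - 4 * s - 1)).astype(int)
        hi = np.minimum(shape, np.ceil(c + 4 * s + 2)).astype(int)
        zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        g = amplitude * np.exp(
            -(
                (zz - c[0]) ** 2 / (2 * s[0] ** 2)
                + (yy - c[1]) ** 2 / (2 * s[1] ** 2)
                + (xx - c[2]) ** 2 / (2 * s[2] ** 2)
            )
        )
        data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += g

    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=shape)
    np.clip(data, 0.0, None, out=data)

    stack = BeadStack(data, voxel_size=(vz, vy, vx))
    truth = SimTruth(bead_centers=centers_arr, fwhm_um=(fz, fy, fx))
    return stack, truth


def simulate_spot_profiles(
    snr_true: float,
    sbr_true: float,
    n: int,
    seed: int | None = 0,
    mu_bg: float = 50.0,
    i_dark: float = 10.0,
    spot_sigma_px: float = 1.5,
) -> tuple[list[LineProfile], SimTruth]:
    """Generate 21-sample spot line profiles realizing requested SNR and SBR.

    SNR and SBR are defined through the *sample* statistics of the 10
    outermost (background) samples after dark subtraction, so the background
    noise vector of each profile is standardized to its exact sample mean and
    standard deviation: mean mu_bg and sd sigma_bg = mu_bg*(sbr-1)/snr.  The
    center sample is sbr*mu_bg.  Randomness enters through the noise shape;
    the measured SNR/SBR of every profile equal the requested values, which
    is exactly what a calibration fixture should deliver.

    The combination is infeasible when the implied sigma_bg <= 0 (snr <= 0 or
    sbr <= 1); sigma_bg -> 0 is degenerate for the sample-sd estimator.
    """
    if snr_true <= 0:
        raise ValueError("snr_true must be > 0")
    if sbr_true <= 1.0:
        raise ValueError(
            "sbr_true must exceed 1 (required background sd would be <= 0)"
        )
    sigma_bg = mu_bg * (sbr_true - 1.0) / snr_true
    rng = np.random.default_rng(seed)
    xs = np.arange(-10, 11)
    bg_idx = np.abs(xs) > 5
    peak = sbr_true * mu_bg  # dark-subtracted center intensity

    profiles: list[LineProfile] = []
    for _ in range(n):
        samples = np.empty(21)
        zvec = rng.normal(size=int(bg_idx.sum()))
        zvec = (zvec - zvec.mean()) / zvec.std(ddof=1)
        samples[bg_idx] = mu_bg + sigma_bg * zvec
        # shoulders: smooth Gaussian flank between peak and background level
        mid = ~bg_idx
        samples[mid] = mu_bg + (peak - mu_bg) * np.exp(
            -(xs[mid] ** 2) / (2.0 * spot_sigma_px**2)
        )
        samples[10] = peak
        if samples.min() < 0:
            raise ValueError(
                "background noise dips below zero intensity; the requested "
                "SNR/SBR needs a larger mu_bg relative to sigma_bg"
            )
        profiles.append(LineProfile(samples + i_dark, i_dark=i_dark))
    return profiles, SimTruth(snr=snr_true, sbr=sbr_true)
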