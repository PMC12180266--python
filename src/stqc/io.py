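"""Shared data model and I/O for imaging spatial transcriptomics (iST) QC.

Coordinate conventions
----------------------
All spatial coordinates are micrometres (µm) with the origin at the image
top-left, x increasing rightward and y downward.  Pixel (row ``i``, col ``j``)
of a segmentation mask covers the half-open square
``[j*s, (j+1)*s) x [i*s, (i+1)*s)`` µm, where ``s`` is the pixel size.  This
makes point-in-pixel tests unambiguous: the pixel containing a point at
``(x, y)`` is ``(floor(y/s), floor(x/s))``.

The z coordinate is carried as a plane index when the source records discrete
imaging planes (Merscope-style) and as µm otherwise; converting between the
two requires an explicit plane spacing and is left to the caller.

Transcript tables are one record per detected molecule (gene id, x/y/z,
optional tile id).  Vendor formats differ only in column naming and coordinate
units, so platform dialects are declarative column maps shipped as data.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

__all__ = [
    "TranscriptTable",
    "ProbePanel",
    "SegmentationMask",
    "CellByGeneMatrix",
    "AssignmentStats",
    "DIALECTS",
    "load_transcripts",
    "write_transcripts",
    "assign_transcripts",
    "crop_region",
]

TRANSCRIPT_COLUMNS = ["gene", "x", "y", "z", "tile_id", "record_id"]


@dataclass(frozen=True)
class Dialect:
    """Declarative column map for one vendor flavour of transcript table.

    ``coords_in_pixels`` marks dialects whose x/y are written in pixels and
    must be converted to µm with an explicit pixel size at load time.
    Unknown extra columns in the source file are ignored.
    """

    gene: str
    x: str
    y: str
    z: str | None = None
    tile_id: str | None = None
    coords_in_pixels: bool = False
    sep: str | None = None  # None -> infer from file extension


#: Platform dialects.  "generic" is this package's own interchange layout,
#: the others mirror the column naming of Molecular Cartography, Merscope and
#: Xenium exports (z is a plane index for MC/Merscope-style files).
DIALECTS: Mapping[str, Dialect] = {
    "generic": Dialect(gene="gene", x="x", y="y", z="z", tile_id="tile_id"),
    "mc": Dialect(gene="gene", x="x", y="y", z="z", coords_in_pixels=True, sep="\t"),
    "merscope": Dialect(
        gene="gene", x="global_x", y="global_y", z="global_z", tile_id="fov"
    ),
    "xenium": Dialect(
        gene="feature_name", x="x_location", y="y_location", z="z_location"
    ),
}


@dataclass
class ProbePanel:
    """Registry of target and background/control probes.

    ``entries`` has columns ``gene_id``, ``kind`` ("target" | "background")
    and ``background_class`` ("false_positive" | "blank" |
    "unassigned_codeword" | "none").  Background entries carry a concrete
    background class; targets carry "none".
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        required = {"gene_id", "kind", "background_class"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel is missing columns: {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id in panel: {dup!r}")
        if not (df["kind"] == "target").any():
            raise ValueError("panel must contain at least one target entry")
        bad = df[(df["kind"] == "background") & (df["background_class"] == "none")]
        if len(bad):
            raise ValueError(
                "background probes must carry a background_class: "
                f"{bad['gene_id'].tolist()}"
            )

    @classmethod
    def from_genes(
        cls,
        targets: Sequence[str],
        backgrounds: Sequence[str] = (),
        background_class: str = "blank",
    ) -> "ProbePanel":
        df = pd.DataFrame(
            {
                "gene_id": list(targets) + list(backgrounds),
                "kind": ["target"] * len(targets) + ["background"] * len(backgrounds),
                "background_class": ["none"] * len(targets)
                + [background_class] * len(backgrounds),
            }
        )
        return cls(df)

    @property
    def target_genes(self) -> list[str]:
        return self.entries.loc[self.entries["kind"] == "target", "gene_id"].tolist()

    @property
    def background_genes(self) -> list[str]:
        return self.entries.loc[
            self.entries["kind"] == "background", "gene_id"
        ].tolist()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.entries["gene_id"])

    @classmethod
    def read(cls, path: str | Path) -> "ProbePanel":
        """Read a two-column delimited panel: ``gene_id, kind[:background_class]``."""
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene_id, spec = (tok.strip() for tok in line.split(",", 1))
            kind, _, bg_class = spec.partition(":")
            rows.append(
                {
                    "gene_id": gene_id,
                    "kind": kind,
                    "background_class": bg_class or "none",
                }
            )
        return cls(pd.DataFrame(rows))

    def write(self, path: str | Path) -> None:
        lines = []
        for row in self.entries.itertuples(index=False):
            spec = row.kind
            if row.background_class != "none":
                spec += f":{row.background_class}"
            lines.append(f"{row.gene_id},{spec}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class TranscriptTable:
    """Point set of detected molecules with gene ids and µm coordinates.

    Backed by a DataFrame with columns ``gene, x, y, z, tile_id, record_id``.
    ``record_id`` is unique; row order is meaningful and preserved by I/O.
    An optional panel allows gene ids to be resolved to target/background.
    """

    df: pd.DataFrame
    panel: ProbePanel | None = None

    def __post_init__(self) -> None:
        df = self.df
        missing = set(TRANSCRIPT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"transcript table missing columns: {sorted(missing)}")
        coords = df[["x", "y"]].to_numpy(dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            bad = int(np.where(~np.isfinite(coords).all(axis=1))[0][0])
            raise ValueError(f"non-finite coordinate at row {bad}")
        if df["record_id"].duplicated().any():
            raise ValueError("record_id values must be unique")
        if self.panel is not None:
            known = set(self.panel.entries["gene_id"])
            unknown = set(df["gene"].unique()) - known
            if unknown:
                raise ValueError(
                    f"gene ids absent from the attached panel: {sorted(unknown)[:5]}"
                )

    @classmethod
    def from_arrays(
        cls,
        gene: Sequence[str],
        x: Sequence[float],
        y: Sequence[float],
        z: Sequence[float] | None = None,
        tile_id: Sequence[int] | None = None,
        panel: ProbePanel | None = None,
    ) -> "TranscriptTable":
        n = len(x)
        df = pd.DataFrame(
            {
                "gene": pd.Series(gene, dtype=object),
                "x": np.asarray(x, dtype=float),
                "y": np.asarray(y, dtype=float),
                "z": np.zeros(n) if z is None else np.asarray(z, dtype=float),
                "tile_id": (
                    pd.array([pd.NA] * n, dtype="Int64")
                    if tile_id is None
                    else pd.array(tile_id, dtype="Int64")
                ),
                "record_id": np.arange(n, dtype=np.int64),
            }
        )
        return cls(df, panel=panel)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates in µm."""
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def subset_genes(self, genes: Sequence[str]) -> "TranscriptTable":
        keep = self.df["gene"].isin(set(genes))
        return TranscriptTable(self.df[keep].reset_index(drop=True), panel=self.panel)


@dataclass
class SegmentationMask:
    """2-D integer label image with its pixel size in µm/pixel.

    Label 0 is background; object ids are positive and need not be contiguous.
    """

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be a 2-D label image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("mask labels must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @classmethod
    def read(cls, path: str | Path, pixel_size: float) -> "SegmentationMask":
        # pixel size is supplied explicitly, never trusted from TIFF tags
        return cls(tifffile.imread(str(path)).astype(np.int32), pixel_size)

    def write(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.labels.astype(np.int32))


@dataclass
class CellByGeneMatrix:
    """Per-cell counts with centroids (µm), areas (µm²) and optional type labels.

    ``counts`` is a cells x genes DataFrame of non-negative integers indexed by
    cell id.  ``centroids`` aligns with ``counts`` and has columns ``x, y``.
    """

    counts: pd.DataFrame
    centroids: pd.DataFrame
    areas: pd.Series | None = None
    cell_type: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.centroids.index):
            raise ValueError("counts and centroids must share the same cell index")

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    def total_counts(self, genes: Sequence[str] | None = None) -> pd.Series:
        cols = self.counts.columns if genes is None else [
            g for g in genes if g in self.counts.columns
        ]
        return self.counts[cols].sum(axis=1)

    def write_mtx(self, prefix: str | Path) -> None:
        """Write MTX triplet plus row (cells) / column (genes) name sidecars."""
        prefix = Path(prefix)
        spio.mmwrite(
            str(prefix.with_suffix(".mtx")),
            sparse.csr_matrix(self.counts.to_numpy()),
        )
        prefix.with_name(prefix.name + "_cells.txt").write_text(
            "\n".join(map(str, self.counts.index)) + "\n"
        )
        prefix.with_name(prefix.name + "_genes.txt").write_text(
            "\n".join(self.counts.columns) + "\n"
        )

    @classmethod
    def read_mtx(
        cls, prefix: str | Path, centroids: pd.DataFrame | None = None
    ) -> "CellByGeneMatrix":
        prefix = Path(prefix)
        mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(np.int64)
        cells = prefix.with_name(prefix.name + "_cells.txt").read_text().split()
        genes = prefix.with_name(prefix.name + "_genes.txt").read_text().split()
        cells = [int(c) for c in cells]
        counts = pd.DataFrame(mat, index=cells, columns=genes)
        if centroids is None:
            centroids = pd.DataFrame(
                np.full((len(cells), 2), np.nan), index=cells, columns=["x", "y"]
            )
        return cls(counts, centroids)


@dataclass(frozen=True)
class AssignmentStats:
    """Bookkeeping for transcript-to-object assignment."""

    n_total: int
    n_assigned: int

    def __post_init__(self) -> None:
        if self.n_assigned > self.n_total:
            raise ValueError("n_assigned cannot exceed n_total")

    @property
    def assigned_fraction(self) -> float:
        return self.n_assigned / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# transcript table I/O


def _read_delimited(path: Path, sep: str | None) -> pd.DataFrame:
    if path.suffix.lower() in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def load_transcripts(
    path: str | Path,
    dialect: str = "generic",
    pixel_size: float | None = None,
    panel: ProbePanel | None = None,
) -> TranscriptTable:
    """Read a transcript table in a named platform dialect.

    Coordinates are converted to µm (``pixel_size`` is required for dialects
    whose coordinates are in pixels).  ``record_id`` is assigned sequentially
    from 0 in file order; row order is preserved.
    """
    if dialect not in DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        )
    spec = DIALECTS[dialect]
    path = Path(path)
    raw = _read_delimited(path, spec.sep)

    for col in (spec.gene, spec.x, spec.y):
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path.name}")

    def _numeric(col: str) -> np.ndarray:
        series = pd.to_numeric(raw[col], errors="coerce")
        bad = series.isna() & raw[col].notna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(
                f"non-numeric value {raw[col].iloc[row]!r} in column {col!r} "
                f"at data row {row}"
            )
        return series.to_numpy(dtype=float)

    x = _numeric(spec.x)
    y = _numeric(spec.y)
    if spec.coords_in_pixels:
        if pixel_size is None:
            raise ValueError(
                f"dialect {dialect!r} stores pixel coordinates; pixel_size required"
            )
        x = x * pixel_size
        y = y * pixel_size
    z = (
        _numeric(spec.z)
        if spec.z is not None and spec.z in raw.columns
        else np.zeros(len(raw))
    )
    tile = (
        pd.array(raw[spec.tile_id], dtype="Int64")
        if spec.tile_id is not None and spec.tile_id in raw.columns
        else pd.array([pd.NA] * len(raw), dtype="Int64")
    )
    df = pd.DataFrame(
        {
            "gene": raw[spec.gene].astype(str),
            "x": x,
            "y": y,
            "z": z,
            "tile_id": tile,
            "record_id": np.arange(len(raw), dtype=np.int64),
        }
    )
    return TranscriptTable(df, panel=panel)


def write_transcripts(tt: TranscriptTable, path: str | Path) -> None:
    """Write a table in the generic dialect (CSV/TSV/Parquet by extension)."""
    path = Path(path)
    out = tt.df[["gene", "x", "y", "z", "tile_id"]]
    if path.suffix.lower() in {".parquet", ".pq"}:
        out.to_parquet(path, index=False)
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# operations


def assign_transcripts(
    tt: TranscriptTable,
    mask: SegmentationMask,
    panel: ProbePanel,
    include_background: bool = False,
) -> tuple[CellByGeneMatrix, AssignmentStats]:
    """Assign transcripts to segmented objects by point-in-pixel containment.

    A transcript at µm position (x, y) maps to mask pixel
    ``(floor(y/s), floor(x/s))``.  Label 0 and out-of-bounds positions count
    as unassigned.  The returned matrix holds counts for panel target genes
    (background probes are excluded unless ``include_background``); assignment
    statistics cover all transcripts regardless of probe kind.

    Centroids are the unweighted mean of member pixel centers times the pixel
    size; areas are pixel counts times the pixel area.
    """
    if not (panel.entries["kind"] == "target").any():
        raise ValueError("panel must contain at least one target gene")
    s = mask.pixel_size
    h, w = mask.labels.shape

    xy = tt.coords
    col = np.floor(xy[:, 0] / s).astype(np.int64) if len(xy) else np.empty(0, int)
    row = np.floor(xy[:, 1] / s).astype(np.int64) if len(xy) else np.empty(0, int)
    inside = (col >= 0) & (col < w) & (row >= 0) & (row < h)
    labels = np.zeros(len(xy), dtype=np.int64)
    labels[inside] = mask.labels[row[inside], col[inside]]
    assigned = labels > 0

    stats = AssignmentStats(n_total=len(xy), n_assigned=int(assigned.sum()))

    genes = list(panel.target_genes)
    if include_background:
        genes += list(panel.background_genes)
    cells = mask.object_ids
    counts = pd.DataFrame(
        np.zeros((len(cells), len(genes)), dtype=np.int64),
        index=pd.Index(cells, name="cell"),
        columns=genes,
    )
    gene_arr = tt.df["gene"].to_numpy()
    sel = assigned & np.isin(gene_arr, np.asarray(genes, dtype=object))
    if sel.any():
        tab = (
            pd.DataFrame({"cell": labels[sel], "gene": gene_arr[sel]})
            .groupby(["cell", "gene"], observed=True)
            .size()
        )
        for (cell, gene), n in tab.items():
            counts.at[cell, gene] = n

    # centroids/areas from the mask itself (pixel centers, µm)
    lab = mask.labels
    flat = lab.ravel()
    nonzero = flat > 0
    order = flat[nonzero]
    rows_px, cols_px = np.divmod(np.nonzero(nonzero)[0], w)
    max_label = int(lab.max()) if lab.size else 0
    npix = np.bincount(order, minlength=max_label + 1)
    sum_r = np.bincount(order, weights=rows_px + 0.5, minlength=max_label + 1)
    sum_c = np.bincount(order, weights=cols_px + 0.5, minlength=max_label + 1)
    with np.errstate(invalid="ignore"):
        cy = sum_r / npix * s
        cx = sum_c / npix * s
    centroids = pd.DataFrame(
        {"x": cx[cells], "y": cy[cells]}, index=counts.index
    )
    areas = pd.Series(npix[cells] * s * s, index=counts.index, name="area")

    return CellByGeneMatrix(counts, centroids, areas=areas), stats


def crop_region(
    tt: TranscriptTable, rect: tuple[float, float, float, float]
) -> TranscriptTable:
    """Keep records with ``xmin <= x < xmax`` and ``ymin <= y < ymax``.

    The rectangle is half-open, so a point exactly at ``xmax`` or ``ymax`` is
    excluded.  Record ids are preserved (cropping is a pure filter).
    """
    xmin, ymin, xmax, ymax = rect
    if not (xmin < xmax and ymin < ymax):
        raise ValueError(f"degenerate crop rectangle: {rect}")
    df = tt.df
    keep = (
        (df["x"] >= xmin) & (df["x"] < xmax) & (df["y"] >= ymin) & (df["y"] < ymax)
    )
    return TranscriptTable(df[keep].reset_index(drop=True), panel=tt.panel)
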