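"""Cross-platform comparison report assembly.

Collects the per-dataset outputs of the metric modules into one summary
table (one row per dataset) plus a machine-readable long-format file.  The
report layer never recomputes a metric: every number is traceable to a
module result and the serialized run configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .imaging import ResolutionSummary
from .sensitivity import SensitivitySummary
from .specificity import FdrResult

__all__ = ["RunConfig", "DatasetMetrics", "build_report", "report_from_long"]


@dataclass
class RunConfig:
    """Run-level configuration serialized into every report for provenance."""

    spot_diameter: float = 55.0  # µm; sets the spatial bin side
    n_strata: int = 4
    nn_quantile: float = 0.95
    dedup_tile_size: float = 2144.0
    dedup_window: float = 30.0
    dedup_max_copies: int = 400
    dedup_min_occurrences: int = 10
    neighborhood_k: int = 10
    neighborhood_n_perm: int = 10_000
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat: dict = {}
        for key, value in data.items():
            if isinstance(value, dict):  # allow [section] grouping
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in flat.items() if k in known})


@dataclass
class DatasetMetrics:
    """Module outputs for one dataset; any field may be missing."""

    sensitivity: SensitivitySummary | None = None
    fdr: FdrResult | None = None
    n_background_range: int | None = None
    n_low_confidence: int | None = None
    resolution: ResolutionSummary | None = None
    assigned_fraction: float | None = None
    duplicate_rate: float | None = None

    def as_flat(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.sensitivity is not None:
            s = self.sensitivity
            out["median_transcripts_per_cell"] = s.median_transcripts
            out["se_transcripts_per_cell"] = s.se_transcripts
            out["median_features_per_cell"] = s.median_features
            out["se_features_per_cell"] = s.se_features
        if self.fdr is not None:
            out["fdr_percent"] = self.fdr.fdr_percent
        if self.n_background_range is not None:
            out["n_background_range_probes"] = float(self.n_background_range)
        if self.n_low_confidence is not None:
            out["n_low_confidence_probes"] = float(self.n_low_confidence)
        if self.resolution is not None:
            out["fwhm_inplane_nm"] = self.resolution.fwhm_inplane_nm
            out["fwhm_inplane_mad_nm"] = self.resolution.mad_inplane_nm
        if self.assigned_fraction is not None:
            out["assigned_fraction"] = self.assigned_fraction
        if self.duplicate_rate is not None:
            out["duplicate_rate"] = self.duplicate_rate
        return out


def build_report(
    results: Mapping[str, DatasetMetrics],
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Assemble the summary table; optionally write summary/long/config files.

    Missing metrics appear as NaN.  The long-format file (dataset, metric,
    value) regenerates the summary exactly via :func:`report_from_long`.
    """
    if not results:
        raise ValueError("no module results to report")
    wide = pd.DataFrame(
        {name: metrics.as_flat() for name, metrics in results.items()}
    ).T
    wide.index.name = "dataset"
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        wide.to_csv(out_dir / "summary.csv")
        long = wide.reset_index().melt(
            id_vars="dataset", var_name="metric", value_name="value"
        )
        long.to_csv(out_dir / "metrics_long.csv", index=False)
        (out_dir / "run_config.json").write_text(
            (config or RunConfig()).to_json() + "\n"
        )
    return wide


def report_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Rebuild the wide summary table from the long-format metric file."""
    wide = long.pivot(index="dataset", columns="metric", values="value")
    wide.columns.name = None
    return wide
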