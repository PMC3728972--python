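"""Reading and writing abundance time-series, configs and run manifests.

Series travel as two-column CSV with header ``year,count`` (years are
integers, counts may be fractional — the simulator works with a scalar
abundance).  Real-data admission applies the monitoring-quality rules: at
least three points, spanning more than five years, with every gap between
successive points under eight years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimeseriesValidationError",
    "read_timeseries",
    "write_timeseries",
    "to_yearly",
    "load_config",
    "RunManifest",
]

MIN_POINTS = 3
MIN_SPAN_YEARS = 5     # span must exceed this
MAX_GAP_YEARS = 8      # gaps must be strictly below this


class TimeseriesValidationError(ValueError):
    """A series violated an admission rule; the message names the rule."""


def read_timeseries(
    path, real_data: bool = False
) -> Tuple[np.ndarray, np.ndarray]:
    """Read a ``year,count`` CSV; returns (years, counts).

    ``real_data=True`` enforces the admission rules (>= 3 points, span > 5
    years, every gap < 8 years) and permits irregular spacing.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["year", "count"]:
        raise TimeseriesValidationError(
            f"expected header 'year,count', got {list(df.columns)!r}"
        )
    df.columns = cols
    if df[["year", "count"]].isna().any().any():
        raise TimeseriesValidationError("malformed rows: missing values")
    years = pd.to_numeric(df["year"], errors="coerce")
    counts = pd.to_numeric(df["count"], errors="coerce")
    if years.isna().any() or counts.isna().any():
        raise TimeseriesValidationError("non-numeric year or count")
    years = years.to_numpy()
    if np.any(years != np.round(years)):
        raise TimeseriesValidationError("years must be integers")
    years = years.astype(int)
    counts = counts.to_numpy(dtype=float)
    if len(np.unique(years)) != len(years):
        raise TimeseriesValidationError("duplicate years")
    order = np.argsort(years)
    years, counts = years[order], counts[order]
    if np.any(counts < 0):
        raise TimeseriesValidationError("negative counts")

    if real_data:
        if len(years) < MIN_POINTS:
            raise TimeseriesValidationError(
                f"minimum of {MIN_POINTS} data points required (got {len(years)})"
            )
        span = years[-1] - years[0]
        if span <= MIN_SPAN_YEARS:
            raise TimeseriesValidationError(
                f"series must span more than {MIN_SPAN_YEARS} years (spans {span})"
            )
        gaps = np.diff(years)
        if gaps.max() >= MAX_GAP_YEARS:
            raise TimeseriesValidationError(
                f"gap of {gaps.max()} years between data points "
                f"(must be < {MAX_GAP_YEARS})"
            )
    return years, counts


def write_timeseries(path, years, counts) -> None:
    """Write a canonical ``year,count`` CSV."""
    df = pd.DataFrame(
        {"year": np.asarray(years, dtype=int), "count": np.asarray(counts, float)}
    )
    df.to_csv(path, index=False)


def to_yearly(years, counts) -> Tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate an irregular series onto a yearly grid."""
    years = np.asarray(years, dtype=int)
    counts = np.asarray(counts, dtype=float)
    grid = np.arange(years[0], years[-1] + 1)
    return grid, np.interp(grid, years, counts)


def load_config(path) -> dict:
    """Scenario configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


@dataclass
class RunManifest:
    """Provenance of one CLI run: config echo, seeds, versions, outputs."""

    command: str
    config: dict
    seed: Optional[int]
    outputs: list = field(default_factory=list)
    row_counts: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.versions:
            import numpy, pandas, scipy

            from . import __version__

            self.versions = {
                "declinewatch": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
            }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))
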