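"""Skyline reconstruction tables and the population size-change ratio.

The second user input is the Bayesian Skyline reconstruction exported from
Tracer: a tab-separated grid of time points (ages before the present) with
posterior summaries of effective population size — mean, median and the
credible-interval bounds (lower/upper).  The test reduces this whole object
to a single number, the size-change ratio

    R = ancestral Ne draw / current Ne draw,

with the ancestral draw taken uniformly from the credible interval at the
oldest time point and the current draw uniformly from the interval at the
most recent time point.  R > 1 means decline toward the present, R < 1
expansion; R = 1 recovers the constant-size model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SkylineFormatError

__all__ = [
    "SkylineTrace",
    "SizeChangeRatio",
    "parse_skyline_table",
    "write_skyline_table",
    "draw_size_change_ratio",
]

REQUIRED_COLUMNS = ("time", "mean", "median", "lower", "upper")


@dataclass(frozen=True)
class SkylineTrace:
    """Posterior Ne summaries on a time grid, sorted ascending in age."""

    time: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        n = self.time.size
        if n < 2:
            raise SkylineFormatError(
                f"skyline table needs at least 2 rows (a current-time and an "
                f"ancestral-time entry), got {n}"
            )
        if np.any(np.diff(self.time) <= 0):
            raise SkylineFormatError("skyline times must be strictly increasing")
        for name in ("mean", "median", "lower", "upper"):
            if np.any(getattr(self, name) <= 0):
                raise SkylineFormatError(f"nonpositive Ne value in column {name!r}")
        if np.any(self.lower > self.median) or np.any(self.median > self.upper):
            raise SkylineFormatError("rows must satisfy lower <= median <= upper")

    @property
    def n_rows(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "mean": self.mean,
                "median": self.median,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass(frozen=True)
class SizeChangeRatio:
    ratio: float
    ancestral_draw: float
    current_draw: float


def _match_columns(columns) -> dict[str, str]:
    mapping: dict[str, str] = {}
    lowered = {c.strip().lower(): c for c in columns}
    for key in REQUIRED_COLUMNS:
        if key in lowered:
            mapping[key] = lowered[key]
            continue
        # Tracer writes e.g. "Upper 95% HPD"; accept a prefix match.
        candidates = [c for low, c in lowered.items() if low.startswith(key)]
        if len(candidates) == 1:
            mapping[key] = candidates[0]
        elif not candidates:
            raise SkylineFormatError(f"missing column: {key}")
        else:
            raise SkylineFormatError(f"ambiguous columns for {key!r}: {candidates}")
    return mapping


def parse_skyline_table(path) -> SkylineTrace:
    """Parse a Tracer-style tab-separated skyline reconstruction table.

    Lines starting with '#' are comments; the header must contain the
    time/mean/median/lower/upper columns (case-insensitive, any order;
    extra columns ignored).  Rows are sorted ascending by time, so the
    minimum-time row is the present.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise SkylineFormatError(f"cannot read skyline table {path}: {exc}") from exc
    if df.shape[1] == 1:
        raise SkylineFormatError(
            "skyline table must be tab-separated with a header row"
        )
    mapping = _match_columns(df.columns)
    data = {}
    for key, col in mapping.items():
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(np.isnan(values))[0]
        if bad.size:
            raise SkylineFormatError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"{col!r}, data row {bad[0] + 1}"
            )
        data[key] = values
    order = np.argsort(data["time"], kind="stable")
    return SkylineTrace(**{k: v[order] for k, v in data.items()})


def write_skyline_table(trace: SkylineTrace, path) -> None:
    """Write a trace in the same tab-separated dialect parsed above."""
    trace.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def draw_size_change_ratio(
    trace: SkylineTrace, rng: np.random.Generator
) -> SizeChangeRatio:
    """Draw ancestral and current Ne from their credible intervals.

    The draw is uniform on [lower, upper] of the oldest-time row (ancestral)
    and of the most-recent-time row (current); zero-width intervals are
    deterministic.
    """
    current = float(rng.uniform(trace.lower[0], trace.upper[0]))
    ancestral = float(rng.uniform(trace.lower[-1], trace.upper[-1]))
    return SizeChangeRatio(
        ratio=ancestral / current, ancestral_draw=ancestral, current_draw=current
    )
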