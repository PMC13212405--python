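"""Detection and binned summary of contiguous missing runs (gaps).

A gap is a maximal run of consecutive missing hours in one channel.  The
census groups gaps into four operationally meaningful duration bins —
short (1–24 h), medium (25–72 h), long (73–120 h) and very long
(121–168 h) — plus an overflow bin for anything longer, and reports count,
mean and maximum duration per bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import StationSeries

#: ordered bin labels and their inclusive hour bounds
BIN_BOUNDS = [("short", 1, 24), ("medium", 25, 72),
              ("long", 73, 120), ("very_long", 121, 168)]
OVERFLOW = ("overflow", 169, None)


@dataclass(frozen=True)
class GapInterval:
    """One maximal missing run: [start, end] inclusive, hourly."""

    variable: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration_h: int

    def __post_init__(self) -> None:
        implied = int((self.end - self.start) / pd.Timedelta(hours=1)) + 1
        if implied != self.duration_h or self.duration_h < 1:
            raise ValueError(
                f"inconsistent gap: start={self.start} end={self.end} "
                f"duration_h={self.duration_h}")


def find_gaps(series: StationSeries, variable: str) -> list[GapInterval]:
    """Maximal missing runs of ``variable``, sorted by start time.

    A fully observed channel yields an empty list.  Runs touching the
    series boundary are reported with their observed (truncated) length.
    """
    if variable not in series.variables:
        raise KeyError(f"unknown variable {variable!r}")
    missing = series.data[variable].isna().to_numpy()
    return [GapInterval(variable, series.data.index[s],
                        series.data.index[e], e - s + 1)
            for s, e in mask_runs(missing)]


def mask_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) integer positions of maximal True runs in a bool mask."""
    if not missing.any():
        return []
    padded = np.concatenate([[False], missing, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def bin_gaps(gaps: list[GapInterval]) -> pd.DataFrame:
    """Census table: one row per duration bin (plus overflow).

    Columns: ``bin, lower_h, upper_h, n_gaps, mean_duration_h,
    max_duration_h``.  Empty bins report mean and max 0.0 by convention.
    Durations above 168 h land in the overflow row, so the counts always
    sum to the number of gaps.
    """
    durations = np.array([g.duration_h for g in gaps], dtype=float)
    rows = []
    for label, lo, hi in BIN_BOUNDS + [OVERFLOW]:
        if hi is None:
            sel = durations >= lo
        else:
            sel = (durations >= lo) & (durations <= hi)
        d = durations[sel]
        rows.append({
            "bin": label, "lower_h": lo, "upper_h": hi if hi is not None else np.inf,
            "n_gaps": int(sel.sum()),
            "mean_duration_h": float(d.mean()) if len(d) else 0.0,
            "max_duration_h": float(d.max()) if len(d) else 0.0,
        })
    return pd.DataFrame(rows)


def write_census(census: pd.DataFrame, path: str | Path) -> None:
    census.to_csv(path, index=False)


def read_census(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
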