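"""Hourly multivariate station series: the exchange object of the pipeline.

A :class:`StationSeries` holds hourly measurements for the ten channels a
road-side air-quality station reports (six pollutants plus temperature,
relative humidity and wind speed), with per-cell missingness (NaN) and a
per-cell provenance tag that distinguishes genuinely observed values from
cells masked by the gap mechanism or by artificial test gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical channel order used in all delimited output
CHANNELS = ["CO", "NO", "NO2", "NOX", "O3", "SO2", "PM", "TEMP", "RH", "WS"]

#: provenance codes (small ints so the frame stays cheap)
OBSERVED = 0
MECHANISM_GAP = 1
ARTIFICIAL_GAP = 2

PROVENANCE_LABELS = {OBSERVED: "observed",
                     MECHANISM_GAP: "mechanism-gap",
                     ARTIFICIAL_GAP: "artificial-gap"}


class StationSeriesError(ValueError):
    """Raised when a series violates its structural invariants."""


@dataclass
class StationSeries:
    """Hourly multivariate series with per-cell missingness and provenance.

    Parameters
    ----------
    data
        Frame indexed by a strictly increasing hourly DatetimeIndex, one
        float column per channel; NaN marks a missing cell.
    provenance
        Same shape as ``data``, int codes from
        :data:`PROVENANCE_LABELS`.  Defaults to all-observed.
    """

    data: pd.DataFrame
    provenance: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                OBSERVED, index=self.data.index, columns=self.data.columns,
                dtype=np.int8)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise StationSeriesError("index must be a DatetimeIndex")
        if len(idx) > 1:
            steps = np.diff(idx.view("i8"))
            if not (steps == 3_600_000_000_000).all():
                raise StationSeriesError(
                    "timestamps must be strictly increasing with a 1 h step")
        if list(self.provenance.columns) != list(self.data.columns) or \
                len(self.provenance) != len(self.data):
            raise StationSeriesError("provenance frame must mirror data frame")

    # -- convenience ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "StationSeries":
        return StationSeries(self.data.copy(), self.provenance.copy())

    def is_complete(self, variables: list[str] | None = None) -> bool:
        cols = variables if variables is not None else self.variables
        return not self.data[cols].isna().any().any()

    def mask_cells(self, variable: str, positions: np.ndarray,
                   code: int) -> pd.Series:
        """Mask ``positions`` (integer locations) of ``variable`` in place.

        Returns the values that were removed, indexed by timestamp.
        """
        col = self.data.columns.get_loc(variable)
        removed = self.data.iloc[positions, col].copy()
        self.data.iloc[positions, col] = np.nan
        self.provenance.iloc[positions, col] = code
        return removed

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write ``timestamp,CO,...,WS`` with empty cells for missing."""
        out = self.data.copy()
        out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
        out.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "StationSeries":
        raw = pd.read_csv(path, parse_dates=["timestamp"])
        raw = raw.set_index("timestamp")
        return cls(raw.astype(float))


def hourly_index(n_hours: int, start: str = "2011-01-01") -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_hours, freq="h")


def ground_truth_frame(variable: str, removed: pd.Series) -> pd.DataFrame:
    """Long-format ground truth: columns variable, timestamp, value."""
    return pd.DataFrame({
        "variable": variable,
        "timestamp": removed.index,
        "value": removed.to_numpy(),
    })


def empty_ground_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=["variable", "timestamp", "value"])


def concat_ground_truth(frames: list[pd.DataFrame]) -> pd.DataFrame:
    frames = [f for f in frames if len(f)]
    if not frames:
        return empty_ground_truth()
    return pd.concat(frames, ignore_index=True)
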