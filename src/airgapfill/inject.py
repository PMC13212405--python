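"""Artificial test-gap injection with placement constraints.

Artificial gaps are contiguous runs deliberately masked from the target
channel (CO) inside fully observed stretches, so the removed values can
later score the imputations.  Placement rules:

* integer lengths drawn uniformly on [min_len, max_len] hours;
* no overlap with pre-existing (mechanism) gaps in the target channel;
* pairwise disjoint with previously placed artificial gaps;
* optionally, every exogenous channel must also be complete inside the gap;
* a warm-up buffer of complete hours must precede each gap so every model
  has a full input window available at the first imputed hour.

Placement is sequential rejection sampling with a bounded retry budget —
simple and reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .census import GapInterval
from .series import (ARTIFICIAL_GAP, StationSeries, concat_ground_truth,
                     empty_ground_truth, ground_truth_frame)


class PlacementError(RuntimeError):
    """Could not place the requested gaps within the retry budget."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} artificial gaps "
            f"before exhausting the retry budget")


@dataclass
class InjectionPlan:
    """Settings for one batch of artificial test gaps (defaults: 46 gaps
    of 25–72 h on CO, 48 h warm-up buffer)."""

    n_gaps: int = 46
    min_len: int = 25
    max_len: int = 72
    target_variable: str = "CO"
    require_complete_exog: bool = True
    buffer_h: int = 48
    seed: int = 0
    max_retries: int = 20000

    def validate(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if self.n_gaps < 0:
            raise ValueError("n_gaps must be >= 0")


@dataclass
class ArtificialGapSet:
    """Placed artificial gaps plus the ground truth of the removed values."""

    gaps: list[GapInterval]
    ground_truth: pd.DataFrame
    plan: InjectionPlan = field(repr=False, default=None)  # type: ignore

    def __len__(self) -> int:
        return len(self.gaps)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "gap_id": range(1, len(self.gaps) + 1),
            "variable": [g.variable for g in self.gaps],
            "start": [g.start for g in self.gaps],
            "end": [g.end for g in self.gaps],
            "duration_h": [g.duration_h for g in self.gaps],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 ground_truth: pd.DataFrame | None = None) -> "ArtificialGapSet":
        t = pd.read_csv(path, parse_dates=["start", "end"])
        gaps = [GapInterval(r.variable, r.start, r.end, int(r.duration_h))
                for r in t.itertuples()]
        gt = ground_truth if ground_truth is not None else empty_ground_truth()
        return cls(gaps, gt, None)


def inject_artificial_gaps(series: StationSeries,
                           plan: InjectionPlan) -> tuple[StationSeries, ArtificialGapSet]:
    """Mask ``plan.n_gaps`` disjoint runs of the target channel.

    Returns the masked series and the :class:`ArtificialGapSet` holding the
    removed values.  Raises :class:`PlacementError` (reporting how many gaps
    were placed) when the series has too little complete, disjoint room.
    """
    plan.validate()
    out = series.copy()
    n = len(out)
    rng = np.random.default_rng(plan.seed)
    index = out.data.index

    target_ok = ~out.data[plan.target_variable].isna().to_numpy()
    if plan.require_complete_exog:
        all_ok = ~out.data.isna().any(axis=1).to_numpy()
    else:
        all_ok = target_ok.copy()

    taken = np.zeros(n, dtype=bool)     # bodies of placed artificial gaps
    reserved = np.zeros(n, dtype=bool)  # their warm-up buffers
    gaps: list[GapInterval] = []
    truths = []
    attempts = 0
    while len(gaps) < plan.n_gaps:
        if attempts >= plan.max_retries:
            raise PlacementError(len(gaps), plan.n_gaps)
        attempts += 1
        length = int(rng.integers(plan.min_len, plan.max_len + 1))
        start = int(rng.integers(0, n))
        stop = start + length
        if stop > n or start < plan.buffer_h:
            continue
        # gap body: fully observed (target + optionally exog), not claimed
        # by another gap's body or warm-up buffer
        if not all_ok[start:stop].all() or taken[start:stop].any() \
                or reserved[start:stop].any():
            continue
        # warm-up buffer before the gap: complete and free of other bodies
        buf = slice(start - plan.buffer_h, start)
        if not all_ok[buf].all() or taken[buf].any():
            continue
        removed = out.mask_cells(plan.target_variable,
                                 np.arange(start, stop), ARTIFICIAL_GAP)
        taken[start:stop] = True
        reserved[buf] = True
        gaps.append(GapInterval(plan.target_variable, index[start],
                                index[stop - 1], length))
        truths.append(ground_truth_frame(plan.target_variable, removed))

    gaps.sort(key=lambda g: g.start)
    return out, ArtificialGapSet(gaps, concat_ground_truth(truths), plan)


def gap_truth(gap_set: ArtificialGapSet, gap: GapInterval) -> pd.Series:
    """Ground-truth values for one gap, indexed by timestamp."""
    gt = gap_set.ground_truth
    sel = ((gt["variable"] == gap.variable) &
           (gt["timestamp"] >= gap.start) & (gt["timestamp"] <= gap.end))
    sub = gt.loc[sel].sort_values("timestamp")
    return pd.Series(sub["value"].to_numpy(),
                     index=pd.DatetimeIndex(sub["timestamp"]))
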