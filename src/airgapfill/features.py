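"""Predictor screening and supervised sample construction.

The screening pipeline mirrors standard practice for multivariate hourly
pollution series: first-difference every channel to remove non-stationary
drift, compute the cross-correlation function of each differenced candidate
predictor against differenced CO at positive lags 0..25 h, and keep the
channels whose peak absolute correlation clears a threshold.

Two supervised representations are built from the (z-score normalized)
series:

* 48-h sliding **windows** for the recurrent networks — for each target
  hour t, the 48 preceding hours of CO plus the selected exogenous
  channels, predicting CO(t);
* explicit **lag rows** for the gradient-boosted trees — CO at lags 12,
  24, 36 and 48 h plus NO2, NO, temperature and relative humidity at t.

Only hours where every required cell is observed enter the samples; hours
inside artificial test gaps never do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inject import ArtificialGapSet
from .series import StationSeries

#: XGBoost-style feature set: CO lags (hours) and contemporaneous exogenous
GBT_CO_LAGS = (12, 24, 36, 48)
GBT_EXOG = ("NO2", "NO", "TEMP", "RH")

#: window-input composition modes for the recurrent networks
INPUT_MODES = ("full_window", "exog_now")


def difference(series: StationSeries, variable: str) -> pd.Series:
    """First difference d(t) = x(t) − x(t−1); missing if either operand is.

    Output is indexed by t (the later hour), length n−1.
    """
    if variable not in series.variables:
        raise KeyError(f"unknown variable {variable!r}")
    x = series.data[variable]
    if len(x) < 2:
        raise ValueError("need at least 2 observations to difference")
    return x.diff().iloc[1:]


def cross_correlation(dx: pd.Series, dy: pd.Series, max_lag: int = 25,
                      min_pairs: int = 30) -> pd.Series:
    """Pearson r between dx(t−τ) and dy(t) for τ = 0..max_lag.

    Lags with fewer than ``min_pairs`` jointly observed pairs, or with zero
    variance in either slice, are reported as NaN.
    """
    x = np.asarray(dx, dtype=float)
    y = np.asarray(dy, dtype=float)
    if len(x) != len(y):
        raise ValueError("dx and dy must have equal length")
    out = np.full(max_lag + 1, np.nan)
    for tau in range(max_lag + 1):
        a = x[:len(x) - tau] if tau else x
        b = y[tau:]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_pairs:
            continue
        aa, bb = a[ok], b[ok]
        sa, sb = aa.std(), bb.std()
        if sa == 0 or sb == 0:
            continue
        out[tau] = float(np.corrcoef(aa, bb)[0, 1])
    return pd.Series(out, index=pd.RangeIndex(max_lag + 1, name="lag_h"))


def ccf_table(series: StationSeries, target: str = "CO",
              predictors: list[str] | None = None,
              max_lag: int = 25) -> pd.DataFrame:
    """CCF of every candidate predictor against the target, after differencing."""
    if predictors is None:
        predictors = [v for v in series.variables if v != target]
    dy = difference(series, target)
    rows = {p: cross_correlation(difference(series, p), dy, max_lag)
            for p in predictors}
    return pd.DataFrame(rows).T


def select_predictors(ccf: pd.DataFrame, threshold: float = 0.2) -> list[str]:
    """Predictors whose peak |r| over the lags clears the threshold,
    ordered by that peak descending; ties broken alphabetically."""
    if ccf.empty:
        raise ValueError("empty CCF table")
    peak = ccf.abs().max(axis=1)
    keep = peak[peak >= threshold]
    return sorted(keep.index, key=lambda v: (-keep[v], v))


class DegenerateVariableError(ValueError):
    """A variable to be normalized has zero variance on the training span."""


@dataclass
class Normalizer:
    """Per-variable z-score parameters estimated on a training span."""

    means: pd.Series
    stds: pd.Series

    @classmethod
    def fit(cls, series: StationSeries, variables: list[str],
            train_span: tuple[pd.Timestamp, pd.Timestamp] | None = None
            ) -> "Normalizer":
        data = series.data[variables]
        if train_span is not None:
            data = data.loc[train_span[0]:train_span[1]]
        n_obs = data.notna().sum()
        if (n_obs < 2).any():
            bad = n_obs[n_obs < 2].index.tolist()
            raise ValueError(f"fewer than 2 observations for {bad}")
        means = data.mean()
        stds = data.std(ddof=1)          # sample sd, n−1 denominator
        if (stds <= 0).any():
            bad = stds[stds <= 0].index.tolist()
            raise DegenerateVariableError(f"zero variance in {bad}")
        return cls(means, stds)

    def apply(self, series: StationSeries) -> StationSeries:
        out = series.copy()
        cols = self.means.index
        out.data[cols] = (out.data[cols] - self.means) / self.stds
        return out

    def apply_values(self, variable: str, values: np.ndarray) -> np.ndarray:
        return (values - self.means[variable]) / self.stds[variable]

    def invert_values(self, variable: str, z: np.ndarray) -> np.ndarray:
        return z * self.stds[variable] + self.means[variable]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"mean": self.means, "std": self.stds}) \
            .rename_axis("variable").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Normalizer":
        t = pd.read_csv(path, index_col="variable")
        return cls(t["mean"], t["std"])


@dataclass
class WindowSet:
    """Stacked 48-h training windows: X (n, window, n_feat), y (n,)."""

    X: np.ndarray
    y: np.ndarray
    t: pd.DatetimeIndex
    feature_names: list[str]
    window: int
    input_mode: str = "full_window"

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class LagRowSet:
    """Explicit lag-feature rows for the tree model."""

    table: pd.DataFrame          # indexed by target timestamp t
    feature_names: list[str] = field(default=None)  # type: ignore

    def __post_init__(self) -> None:
        if self.feature_names is None:
            self.feature_names = [c for c in self.table.columns if c != "target"]

    def __len__(self) -> int:
        return len(self.table)

    @property
    def X(self) -> np.ndarray:
        return self.table[self.feature_names].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.table["target"].to_numpy()


def _excluded_positions(index: pd.DatetimeIndex,
                        exclusions: ArtificialGapSet | None) -> np.ndarray:
    bad = np.zeros(len(index), dtype=bool)
    if exclusions is not None:
        for g in exclusions.gaps:
            bad |= (index >= g.start) & (index <= g.end)
    return bad


def build_windows(series: StationSeries, predictors: list[str],
                  window: int = 48,
                  exclusions: ArtificialGapSet | None = None,
                  target: str = "CO",
                  input_mode: str = "full_window") -> WindowSet:
    """One sample per hour t whose full input block and target are observed.

    ``input_mode='full_window'`` feeds the 48-h block of CO and every
    selected exogenous channel; ``'exog_now'`` feeds the 48-h CO block with
    the exogenous values at t held constant across the window.
    """
    if input_mode not in INPUT_MODES:
        raise ValueError(f"input_mode must be one of {INPUT_MODES}")
    channels = [target] + [p for p in predictors if p != target]
    V = series.data[channels].to_numpy()
    n, m = V.shape
    index = series.data.index
    if n <= window:
        return WindowSet(np.empty((0, window, m)), np.empty(0),
                         index[:0], channels, window, input_mode)

    # block for target position p (p >= window) starts at p-window
    blocks = np.lib.stride_tricks.sliding_window_view(V, window, axis=0)
    blocks = blocks[:-1]                       # drop block ending at the last hour
    blocks = np.swapaxes(blocks, 1, 2)         # (n-window, window, m)
    targets = V[window:, 0]
    tgt_index = index[window:]

    if input_mode == "full_window":
        finite_block = np.isfinite(blocks).all(axis=(1, 2))
        X_all = blocks
    else:
        finite_co = np.isfinite(blocks[:, :, 0]).all(axis=1)
        exog_now = V[window:, 1:]
        finite_block = finite_co & np.isfinite(exog_now).all(axis=1)
        X_all = np.concatenate(
            [blocks[:, :, :1],
             np.repeat(exog_now[:, None, :], window, axis=1)], axis=2)

    ok = finite_block & np.isfinite(targets)
    ok &= ~_excluded_positions(tgt_index, exclusions)
    return WindowSet(np.ascontiguousarray(X_all[ok]), targets[ok],
                     tgt_index[ok], channels, window, input_mode)


def build_lag_rows(series: StationSeries,
                   exclusions: ArtificialGapSet | None = None,
                   target: str = "CO",
                   co_lags: tuple[int, ...] = GBT_CO_LAGS,
                   exog: tuple[str, ...] = GBT_EXOG) -> LagRowSet:
    """Rows with CO at the configured lags, exogenous channels at t, and
    the CO target; only rows with all cells observed are kept."""
    co = series.data[target]
    cols = {f"{target}_lag{lag}": co.shift(lag) for lag in co_lags}
    cols.update({e: series.data[e] for e in exog})
    cols["target"] = co
    table = pd.DataFrame(cols, index=series.data.index)
    table = table.iloc[max(co_lags):]          # ensure t−max_lag exists
    ok = table.notna().all(axis=1).to_numpy()
    ok &= ~_excluded_positions(table.index, exclusions)
    return LagRowSet(table.loc[ok])
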