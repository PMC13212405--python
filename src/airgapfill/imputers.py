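"""Model training and recursive multi-step gap imputation.

Three model families fill CO gaps:

* **gbt** — gradient-boosted regression trees (XGBoost; 600 trees, depth 6,
  learning rate 0.05, squared-error loss) on explicit CO lags (12/24/36/48 h)
  plus NO2, NO, temperature and relative humidity at the current hour;
* **lstm** — stacked LSTM (64, 32 recurrent units, 64 ReLU dense head);
* **rnn** — stacked simple RNN with sigmoid units (128, 64, 128 ReLU head);

both networks are trained for one-step-ahead prediction of normalized CO
from 48-h multivariate windows (MSE loss, Adam).

A gap is imputed hour by hour in chronological order; once an hour is
filled, its value is fed back into the lag features / input window for the
following hours (recursive multi-step scheme).  Hours whose CO inputs were
themselves imputed are flagged.  Exogenous channels are read from the
observed series inside the gap (artificial gaps never mask them); where a
mechanism gap makes one unavailable, the last observation is carried
forward and the hour is flagged.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .census import GapInterval
from .features import (GBT_CO_LAGS, GBT_EXOG, LagRowSet, Normalizer,
                       WindowSet)
from .nets import SequenceRegressor
from .series import StationSeries

ARTIFACT_FORMAT_VERSION = 1


@dataclass
class GBTSpec:
    """Gradient-boosted-tree configuration (fixed, no tuning)."""

    n_trees: int = 600
    max_depth: int = 6
    learning_rate: float = 0.05

    def validate(self) -> None:
        if min(self.n_trees, self.max_depth) <= 0 or self.learning_rate <= 0:
            raise ValueError("GBT spec fields must be positive")


@dataclass
class NetSpec:
    """Recurrent-network configuration.

    ``kind`` selects the architecture ('lstm': 64/32 recurrent units with a
    64-unit ReLU head; 'rnn': 128/64 sigmoid units with a 128-unit head).
    Training-loop settings (epochs, batch size, early stopping) are not
    part of the architecture and are exposed here with pragmatic defaults.
    """

    kind: str = "lstm"
    units: tuple[int, int, int] | None = None
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    validation_split: float = 0.1
    patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("lstm", "rnn"):
            raise ValueError("kind must be 'lstm' or 'rnn'")


class SampleSizeError(ValueError):
    """Too few training samples for the requested model."""


class WarmupError(ValueError):
    """Insufficient complete history immediately before a gap."""


@dataclass
class TrainedImputer:
    """A fitted model plus everything needed to run it coherently."""

    family: str                       # 'gbt' | 'lstm' | 'rnn'
    model: object
    normalizer: Normalizer
    predictors: list[str]             # exogenous channels (nets) or GBT exog
    input_mode: str = "full_window"
    window: int = 48
    co_lags: tuple[int, ...] = GBT_CO_LAGS
    history: dict = field(default_factory=dict, repr=False)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format_version": ARTIFACT_FORMAT_VERSION,
                         "imputer": self}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedImputer":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if blob.get("format_version") != ARTIFACT_FORMAT_VERSION:
            raise ValueError("unsupported model artifact version")
        return blob["imputer"]


def train_gbt(rows: LagRowSet, spec: GBTSpec, seed: int,
              normalizer: Normalizer) -> TrainedImputer:
    """Fit the tree model on normalized lag rows (needs >= 100 rows)."""
    spec.validate()
    if len(rows) < 100:
        raise SampleSizeError(f"need >= 100 lag rows, got {len(rows)}")
    model = xgb.XGBRegressor(
        n_estimators=spec.n_trees, max_depth=spec.max_depth,
        learning_rate=spec.learning_rate, objective="reg:squarederror",
        random_state=int(seed) % (2 ** 31), n_jobs=1, tree_method="hist",
        verbosity=0)
    model.fit(rows.X, rows.y)
    exog = tuple(c for c in rows.feature_names if not c.startswith("CO_lag"))
    lags = tuple(int(c.split("lag")[1]) for c in rows.feature_names
                 if c.startswith("CO_lag"))
    return TrainedImputer("gbt", model, normalizer, list(exog),
                          co_lags=lags)


def train_network(samples: WindowSet, spec: NetSpec,
                  normalizer: Normalizer) -> TrainedImputer:
    """Fit a recurrent network for one-step-ahead normalized-CO prediction
    (needs >= 500 windows)."""
    spec.validate()
    if len(samples) < 500:
        raise SampleSizeError(f"need >= 500 window samples, got {len(samples)}")
    rng = np.random.default_rng(spec.seed)
    net = SequenceRegressor.build(spec.kind, samples.X.shape[2], rng,
                                  units=spec.units)
    history = net.fit(samples.X, samples.y, epochs=spec.epochs,
                      batch_size=spec.batch_size, lr=spec.lr, seed=spec.seed,
                      validation_split=spec.validation_split,
                      patience=spec.patience)
    exog = [c for c in samples.feature_names[1:]]
    return TrainedImputer(spec.kind, net, normalizer, exog,
                          input_mode=samples.input_mode,
                          window=samples.window, history=history)


@dataclass
class ImputationResult:
    """Per-hour imputed CO for one gap, de-normalized to ppm."""

    gap_id: int
    family: str
    values: pd.Series                 # indexed by timestamp, ppm
    used_imputed_inputs: np.ndarray   # bool flag per hour

    def __len__(self) -> int:
        return len(self.values)


def impute_gap(imputer: TrainedImputer, series: StationSeries,
               gap: GapInterval, gap_id: int = 0,
               exog_fallback: str = "locf") -> ImputationResult:
    """Fill one gap recursively, never reading CO observed after gap.start.

    The warm-up history (the ``window`` / max-lag hours before the gap)
    must be complete for all required channels.  Exogenous values inside
    the gap come from the observed series; a missing exogenous cell is
    carried forward from the last observation when ``exog_fallback='locf'``
    (with a warning), otherwise it is an error.
    """
    index = series.data.index
    p0 = index.get_loc(gap.start)
    p1 = index.get_loc(gap.end)
    L = p1 - p0 + 1
    if L <= 0 or gap.duration_h == 0:
        return ImputationResult(gap_id, imputer.family,
                                pd.Series(dtype=float), np.zeros(0, bool))

    norm = imputer.normalizer
    warmup = imputer.window if imputer.family != "gbt" else max(imputer.co_lags)
    if p0 - warmup < 0:
        raise WarmupError(f"gap at {gap.start} needs {warmup} h of history")

    # normalized working CO: observed values; gap hours filled as we go
    co_raw = series.data["CO"].to_numpy().copy()
    z_co = norm.apply_values("CO", co_raw)
    if np.isnan(z_co[p0 - warmup:p0]).any():
        raise WarmupError(f"incomplete CO history in the {warmup} h before "
                          f"{gap.start}")

    # normalized exogenous block covering warm-up + gap, LOCF fallback
    exog_names = imputer.predictors
    Z = np.empty((len(index), len(exog_names)))
    fellback = np.zeros(len(index), dtype=bool)
    for j, name in enumerate(exog_names):
        col = norm.apply_values(name, series.data[name].to_numpy())
        nan_here = np.isnan(col)
        if nan_here[p0 - warmup:p1 + 1].any():
            if exog_fallback != "locf":
                raise ValueError(f"missing exogenous {name} inside/around gap "
                                 f"{gap_id} and no fallback configured")
            warnings.warn(f"exogenous {name} missing near gap {gap_id}; "
                          f"carrying last observation forward")
            filled = pd.Series(col).ffill().bfill().to_numpy()
            fellback |= nan_here
            col = filled
        Z[:, j] = col

    preds = np.empty(L)
    flags = np.zeros(L, dtype=bool)
    for k in range(L):
        p = p0 + k
        if imputer.family == "gbt":
            lag_pos = [p - lag for lag in imputer.co_lags]
            x = np.concatenate([z_co[lag_pos], Z[p]])[None, :]
            z_pred = float(imputer.model.predict(x)[0])
            flags[k] = any(pos >= p0 for pos in lag_pos) or fellback[p]
        else:
            w = imputer.window
            co_win = z_co[p - w:p][:, None]
            if imputer.input_mode == "full_window":
                xw = np.concatenate([co_win, Z[p - w:p]], axis=1)
                flags[k] = (p - w < p1 + 1 and p - w >= p0) or k > 0 \
                    or fellback[p - w:p].any()
            else:
                xw = np.concatenate(
                    [co_win, np.repeat(Z[p][None, :], w, axis=0)], axis=1)
                flags[k] = k > 0 or fellback[p]
            z_pred = float(imputer.model.predict(xw[None, :, :])[0])
        z_co[p] = z_pred
        preds[k] = z_pred

    values = norm.invert_values("CO", preds)
    return ImputationResult(gap_id, imputer.family,
                            pd.Series(values, index=index[p0:p1 + 1]),
                            flags)


def write_imputations(results: list[ImputationResult],
                      path: str | Path) -> None:
    rows = []
    for r in results:
        for ts, v, fl in zip(r.values.index, r.values.to_numpy(),
                             r.used_imputed_inputs):
            rows.append({"gap_id": r.gap_id, "timestamp": ts,
                         "model": r.family, "imputed_ppm": v,
                         "used_imputed_inputs": bool(fl)})
    pd.DataFrame(rows).to_csv(path, index=False)
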