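"""Seeded synthetic road-side station generator.

Real CO records from urban kerbside monitors show a double-peaked
(rush-hour) diurnal cycle, a weaker weekly cycle, short-memory
autocorrelated noise, strong contemporaneous correlation with the nitrogen
oxides (co-emitted by traffic), anticorrelation with ozone (titration), and
gap runs dominated by short (< 1 day) outages.  The generator reproduces
exactly that structure:

``CO(t) = co_base + diurnal(t) + weekly(t) + AR(1) noise``

with each coupled channel ``gain * (CO signal - co_base) + base + own
noise``, temperature a single diurnal harmonic, and relative humidity in
anti-phase with temperature.  Missing runs are then injected under an MCAR
or MAR mechanism (MAR: outage probability increases with observed relative
humidity, never with the masked value itself) with run lengths drawn from a
four-bin duration distribution.

Each channel draws from its own PRNG stream spawned from the master seed,
so adding a channel never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .series import (CHANNELS, MECHANISM_GAP, StationSeries,
                     concat_ground_truth, empty_ground_truth,
                     ground_truth_frame, hourly_index)

#: (lower, upper) inclusive hour bounds of the four gap-duration bins
GAP_BINS = {"short": (1, 24), "medium": (25, 72),
            "long": (73, 120), "very_long": (121, 168)}

NONNEGATIVE = ["CO", "NO", "NO2", "NOX", "O3", "SO2", "PM", "WS"]


class ConfigError(ValueError):
    """A synthetic-station configuration field is invalid."""


@dataclass
class SyntheticConfig:
    """Generative settings for one synthetic station.

    ``diurnal_amps`` are the amplitudes (ppm) of a 24 h harmonic and a 12 h
    harmonic whose phases are fixed to put peaks near the 07:00 and 19:00
    rush hours.  ``couplings`` maps a channel name to
    ``(gain on the CO signal, sd of its own white noise, base level)``.
    ``gap_rate`` is the expected number of mechanism gaps per 1000 hours,
    per gapped channel; ``gap_len_dist`` gives the probability of each
    duration bin (lengths uniform within the bin).
    """

    n_hours: int = 2 * 8760
    seed: int = 0
    co_base: float = 0.6
    diurnal_amps: tuple[float, ...] = (0.12, 0.22)
    weekly_amp: float = 0.05
    ar_coef: float = 0.6
    noise_sd: float = 0.08
    couplings: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "NO": (0.80, 0.06, 0.10),
            "NO2": (0.70, 0.08, 0.20),
            "NOX": (0.90, 0.05, 0.30),
            "O3": (-0.60, 0.08, 0.50),
            "SO2": (0.10, 0.05, 0.05),
            "PM": (0.25, 0.10, 0.30),
            "WS": (-0.20, 0.30, 2.00),
        })
    o3_sign: int = -1
    mechanism: str = "MAR"
    gap_rate: float = 2.0
    gap_len_dist: dict[str, float] = field(
        default_factory=lambda: {"short": 0.90, "medium": 0.07,
                                 "long": 0.03, "very_long": 0.0})
    mar_covariate: str = "RH"
    mar_strength: float = 1.5
    gapped_channels: tuple[str, ...] = ("CO", "NO", "NO2", "NOX", "O3",
                                        "SO2", "PM", "TEMP", "RH", "WS")

    def validate(self) -> None:
        if self.n_hours < 168:
            raise ConfigError("n_hours must be >= 168 (one full week)")
        if not abs(self.ar_coef) < 1:
            raise ConfigError("ar_coef must satisfy |ar_coef| < 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ConfigError(f"mechanism must be MCAR or MAR, "
                              f"got {self.mechanism!r}")
        if self.gap_rate < 0:
            raise ConfigError("gap_rate must be >= 0")
        total = sum(self.gap_len_dist.values())
        if self.gap_len_dist and not np.isclose(total, 1.0):
            raise ConfigError("gap_len_dist probabilities must sum to 1")
        for key in self.gap_len_dist:
            if key not in GAP_BINS:
                raise ConfigError(f"unknown gap bin {key!r}")
        if np.sign(self.couplings.get("O3", (-1, 0, 0))[0]) not in (0, self.o3_sign):
            raise ConfigError("O3 coupling gain must match o3_sign (negative)")


def _channel_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One independent PRNG stream per channel plus one for the mechanism."""
    names = CHANNELS + ["mechanism"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, size=n)
    # x_t = phi x_{t-1} + eps_t, stationary start
    x = lfilter([1.0], [1.0, -phi], eps)
    return x


def co_seasonal_template(index: pd.DatetimeIndex, cfg: SyntheticConfig) -> np.ndarray:
    """Deterministic CO component: base + double-peak diurnal + weekly."""
    h = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    t = np.arange(len(index), dtype=float)
    s = np.full(len(index), cfg.co_base)
    amps = cfg.diurnal_amps
    if len(amps) > 0:   # 24 h harmonic, trough overnight
        s = s + amps[0] * np.cos(2 * np.pi * (h - 13.0) / 24.0)
    if len(amps) > 1:   # 12 h harmonic -> peaks near 07:00 and 19:00
        s = s + amps[1] * np.cos(2 * np.pi * (h - 7.0) / 12.0)
    for k, a in enumerate(amps[2:], start=3):
        s = s + a * np.cos(2 * np.pi * k * (h - 7.0) / 24.0)
    s = s + cfg.weekly_amp * np.cos(2 * np.pi * t / 168.0)
    return s


def generate_station(cfg: SyntheticConfig) -> StationSeries:
    """Generate a fully complete synthetic station series.

    The returned series has no missing cells; use
    :func:`inject_mechanism_gaps` to impose the outage pattern.
    """
    cfg.validate()
    rngs = _channel_rngs(cfg.seed)
    index = hourly_index(cfg.n_hours)
    n = cfg.n_hours
    h = index.hour.to_numpy().astype(float)

    template = co_seasonal_template(index, cfg)
    co_noise = _ar1(rngs["CO"], n, cfg.ar_coef, cfg.noise_sd)
    co_signal = template + co_noise          # before clipping: the coupling source

    data = {}
    data["CO"] = np.clip(co_signal, 0.0, None)

    anomaly = co_signal - cfg.co_base        # shared traffic-driven signal
    for name, (gain, own_sd, base) in cfg.couplings.items():
        own = rngs[name].normal(0.0, own_sd, size=n) if own_sd > 0 else 0.0
        data[name] = base + gain * anomaly + own

    # temperature: single diurnal harmonic peaking mid-afternoon
    temp_noise = _ar1(rngs["TEMP"], n, 0.8, 0.3)
    data["TEMP"] = 26.0 + 3.0 * np.cos(2 * np.pi * (h - 15.0) / 24.0) + temp_noise
    # relative humidity in anti-phase with temperature
    rh_noise = _ar1(rngs["RH"], n, 0.8, 1.5)
    data["RH"] = np.clip(
        78.0 - 10.0 * np.cos(2 * np.pi * (h - 15.0) / 24.0) + rh_noise, 0.0, 100.0)

    for name in NONNEGATIVE:
        if name in data:
            data[name] = np.clip(data[name], 0.0, None)

    frame = pd.DataFrame({c: data[c] for c in CHANNELS}, index=index)
    return StationSeries(frame)


def _draw_gap_length(rng: np.random.Generator, cfg: SyntheticConfig) -> int:
    labels = list(cfg.gap_len_dist.keys())
    probs = np.array([cfg.gap_len_dist[k] for k in labels])
    label = labels[rng.choice(len(labels), p=probs / probs.sum())]
    lo, hi = GAP_BINS[label]
    return int(rng.integers(lo, hi + 1))


class GapPlacementError(RuntimeError):
    """Feasible gap placement could not be found within the retry budget."""


def inject_mechanism_gaps(series: StationSeries, cfg: SyntheticConfig,
                          max_retries: int = 200) -> tuple[StationSeries, pd.DataFrame]:
    """Mask whole contiguous runs per channel under MCAR or MAR.

    MCAR draws gap starts uniformly over time; MAR weights the start
    probability by a logistic function of the observed MAR covariate
    (relative humidity by default) — never by the masked value itself.
    Returns the masked series and the ground truth of removed cells.
    """
    cfg.validate()
    if not series.is_complete():
        raise ValueError("inject_mechanism_gaps expects a complete series")
    out = series.copy()
    n = len(out)
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(len(CHANNELS) + 1)[-1])

    if cfg.gap_rate == 0 or not cfg.gap_len_dist or \
            sum(cfg.gap_len_dist.values()) == 0:
        return out, empty_ground_truth()

    if cfg.mechanism == "MAR":
        cov = series.data[cfg.mar_covariate].to_numpy()
        z = (cov - cov.mean()) / (cov.std() or 1.0)
        weights = 1.0 / (1.0 + np.exp(-cfg.mar_strength * z))
    else:
        weights = np.ones(n)
    weights = weights / weights.sum()

    truths = []
    for variable in cfg.gapped_channels:
        n_gaps = rng.poisson(cfg.gap_rate * n / 1000.0)
        taken = np.zeros(n, dtype=bool)
        placed = 0
        attempts = 0
        while placed < n_gaps:
            if attempts > max_retries * max(n_gaps, 1):
                raise GapPlacementError(
                    f"placed only {placed}/{n_gaps} gaps on {variable}")
            attempts += 1
            length = _draw_gap_length(rng, cfg)
            start = int(rng.choice(n, p=weights))
            if start + length > n or taken[start:start + length].any():
                continue
            taken[start:start + length] = True
            removed = out.mask_cells(
                variable, np.arange(start, start + length), MECHANISM_GAP)
            truths.append(ground_truth_frame(variable, removed))
            placed += 1
    return out, concat_ground_truth(truths)
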