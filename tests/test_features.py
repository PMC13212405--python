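"""Differencing, CCF screening, normalization, sample construction."""

import numpy as np
import pandas as pd
import pytest

from airgapfill.features import (DegenerateVariableError, Normalizer,
                                 build_lag_rows, build_windows, ccf_table,
                                 cross_correlation, difference,
                                 select_predictors)
from airgapfill.inject import InjectionPlan, inject_artificial_gaps
from airgapfill.synthetic import SyntheticConfig, generate_station

from conftest import station_from_values


# ---- differencing ------------------------------------------------------

def test_difference_constant_is_zero():
    s = station_from_values({"CO": np.full(10, 3.5)})
    assert (difference(s, "CO") == 0).all()


def test_difference_hand_example():
    s = station_from_values({"CO": np.array([1.0, 3.0, 2.0])})
    np.testing.assert_array_equal(difference(s, "CO").to_numpy(), [2.0, -1.0])


def test_difference_missing_propagates():
    co = np.arange(10, dtype=float)
    co[5] = np.nan
    d = difference(station_from_values({"CO": co}), "CO")
    # d is indexed by the later hour: positions 5 and 6 of the original
    assert np.isnan(d.iloc[4]) and np.isnan(d.iloc[5])
    assert d.isna().sum() == 2


def test_difference_cumsum_reconstructs():
    rng = np.random.default_rng(3)
    x = rng.normal(size=200).cumsum()
    s = station_from_values({"CO": x})
    d = difference(s, "CO").to_numpy()
    np.testing.assert_allclose(x[0] + np.concatenate([[0], d]).cumsum(),
                               x, atol=1e-12)


# ---- cross-correlation -------------------------------------------------

def test_ccf_self_correlation_is_one():
    rng = np.random.default_rng(1)
    d = pd.Series(rng.normal(size=500))
    r = cross_correlation(d, d)
    assert r[0] == pytest.approx(1.0, abs=1e-12)


def test_ccf_pure_shift_peaks_at_three():
    rng = np.random.default_rng(2)
    x = pd.Series(rng.normal(size=800))
    y = x.shift(3)
    r = cross_correlation(x, y)
    assert abs(r[3] - 1.0) < 1e-12
    assert r.idxmax() == 3


def test_ccf_white_noise_small_everywhere():
    hits = 0
    for seed in range(30):
        rng = np.random.default_rng(seed)
        x = pd.Series(rng.normal(size=5000))
        y = pd.Series(rng.normal(size=5000))
        if cross_correlation(x, y).abs().max() < 0.05:
            hits += 1
    assert hits >= 27


def test_ccf_affine_invariance():
    rng = np.random.default_rng(5)
    x = pd.Series(rng.normal(size=600))
    y = pd.Series(rng.normal(size=600) + 0.5 * x)
    r1 = cross_correlation(x, y)
    r2 = cross_correlation(3.0 * x + 7.0, -2.0 * y + 1.0)
    np.testing.assert_allclose(r1.abs(), r2.abs(), atol=1e-12)


def test_ccf_too_few_pairs_undefined():
    x = pd.Series(np.random.default_rng(0).normal(size=40))
    r = cross_correlation(x, x, max_lag=25)
    assert np.isnan(r[20])           # only 20 pairs at lag 20


# ---- predictor selection -----------------------------------------------

def test_select_predictors_generator_implied():
    series = generate_station(SyntheticConfig(n_hours=8760, seed=6,
                                              gap_rate=0.0))
    tbl = ccf_table(series)
    chosen = select_predictors(tbl, threshold=0.2)
    assert "NO" in chosen
    assert "SO2" not in chosen       # near-zero coupling gain


def test_select_predictors_threshold_zero_returns_all_ordered():
    series = generate_station(SyntheticConfig(n_hours=3000, seed=6,
                                              gap_rate=0.0))
    tbl = ccf_table(series)
    chosen = select_predictors(tbl, threshold=0.0)
    assert set(chosen) == set(tbl.index)
    peaks = tbl.abs().max(axis=1)
    assert all(peaks[a] >= peaks[b] - 1e-12
               for a, b in zip(chosen, chosen[1:]))


def test_select_predictors_all_below_threshold():
    tbl = pd.DataFrame({0: [0.01, 0.02]}, index=["A", "B"])
    assert select_predictors(tbl, threshold=0.5) == []


# ---- normalization -----------------------------------------------------

def test_normalizer_round_trip(small_station):
    norm = Normalizer.fit(small_station, ["CO", "NO"])
    z = norm.apply_values("CO", small_station.data["CO"].to_numpy())
    back = norm.invert_values("CO", z)
    np.testing.assert_allclose(back, small_station.data["CO"].to_numpy(),
                               atol=1e-12)
    assert norm.apply_values("CO", np.array([norm.means["CO"]]))[0] == \
        pytest.approx(0.0, abs=1e-12)


def test_normalizer_sample_sd_convention():
    """x=[0,10]: with the n-1 denominator, sd=sqrt(50) so z=+-1/sqrt(2)."""
    s = station_from_values({"CO": np.array([0.0, 10.0])})
    norm = Normalizer.fit(s, ["CO"])
    z = norm.apply_values("CO", np.array([0.0, 10.0]))
    np.testing.assert_allclose(z, [-1 / np.sqrt(2), 1 / np.sqrt(2)],
                               atol=1e-12)


def test_normalizer_degenerate_variable():
    s = station_from_values({"CO": np.full(20, 2.0)})
    with pytest.raises(DegenerateVariableError):
        Normalizer.fit(s, ["CO"])


def test_normalizer_csv_round_trip(tmp_path, small_station):
    norm = Normalizer.fit(small_station, ["CO", "NO", "TEMP"])
    path = tmp_path / "norm.csv"
    norm.to_csv(path)
    back = Normalizer.from_csv(path)
    pd.testing.assert_series_equal(norm.means, back.means,
                                   check_names=False)


# ---- supervised samples ------------------------------------------------

def test_window_count_on_complete_series():
    s = station_from_values({"CO": np.random.default_rng(0).normal(size=100)})
    ws = build_windows(s, ["NO"], window=48)
    assert len(ws) == 52             # targets at hours 49..100
    assert ws.X.shape == (52, 48, 2)


def test_windows_all_missing_series():
    s = station_from_values({"CO": np.full(100, np.nan)})
    assert len(build_windows(s, ["NO"], window=48)) == 0


def test_lag_row_count_on_complete_series():
    s = station_from_values({"CO": np.random.default_rng(0).normal(size=100)})
    rows = build_lag_rows(s)
    assert len(rows) == 52
    assert rows.X.shape[1] == 8      # 4 CO lags + 4 exogenous


def test_lag_row_excludes_missing_lag():
    co = np.random.default_rng(1).normal(size=120)
    co[60] = np.nan                  # kills targets at 60 and t-lag hits
    s = station_from_values({"CO": co})
    rows = build_lag_rows(s)
    affected = {60, 72, 84, 96, 108}
    got_positions = {s.data.index.get_loc(t) for t in rows.table.index}
    assert affected.isdisjoint(got_positions)


def test_lag_rows_never_exceed_window_samples():
    rng = np.random.default_rng(8)
    for _ in range(10):
        co = rng.normal(size=300)
        co[rng.random(300) < 0.1] = np.nan
        s = station_from_values({"CO": co})
        n_rows = len(build_lag_rows(s))
        n_win = len(build_windows(s, ["NO", "NO2", "TEMP", "RH"], window=48))
        assert n_rows >= n_win       # windows need 48 consecutive CO hours


def test_no_sample_touches_artificial_gaps():
    series = generate_station(SyntheticConfig(n_hours=5000, seed=12,
                                              gap_rate=0.0))
    gapped, gap_set = inject_artificial_gaps(series,
                                             InjectionPlan(n_gaps=6, seed=3))
    norm = Normalizer.fit(gapped, ["CO", "NO", "NO2", "TEMP", "RH"])
    normalized = norm.apply(gapped)
    ws = build_windows(normalized, ["NO"], exclusions=gap_set)
    rows = build_lag_rows(normalized, exclusions=gap_set)
    gap_hours = set()
    for g in gap_set.gaps:
        gap_hours.update(pd.date_range(g.start, g.end, freq="h"))
    assert gap_hours.isdisjoint(ws.t)
    assert gap_hours.isdisjoint(rows.table.index)
    # windows end strictly before their target, so none may *cover* a gap
    for t in ws.t:
        block = pd.date_range(t - pd.Timedelta(hours=48), t, freq="h")[:-1]
        assert np.isfinite(
            normalized.data.loc[block, ["CO"]].to_numpy()).all()


def test_exog_now_mode_shapes():
    s = station_from_values(
        {"CO": np.random.default_rng(0).normal(size=200)})
    ws = build_windows(s, ["NO", "TEMP"], window=48, input_mode="exog_now")
    assert ws.X.shape == (152, 48, 3)
    # exogenous channels constant across the window
    assert (ws.X[:, :, 1].std(axis=1) == 0).all()
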