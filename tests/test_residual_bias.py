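"""The residual-bias certification procedure and its components."""

import numpy as np
import pytest
from scipy import stats

from airgapfill.residual_bias import (StatsConfig, assess_gap_bias,
                                      block_bootstrap_mean_p, ljung_box,
                                      newey_west_mean_p, summarize_bias,
                                      t_zero_mean)


def ar1(rng, n, phi, mean=0.0, sd=1.0):
    x = np.empty(n)
    x[0] = rng.normal(0, sd / np.sqrt(1 - phi ** 2))
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal(0, sd)
    return x + mean


# ---- Ljung-Box ---------------------------------------------------------

def test_ljung_box_alternating_residuals():
    r = np.tile([1.0, -1.0], 20)
    Q, p = ljung_box(r, 10)
    assert p < 1e-10


def test_ljung_box_precondition():
    with pytest.raises(ValueError):
        ljung_box(np.ones(11), 10)


def test_ljung_box_matches_statsmodels():
    from statsmodels.stats.diagnostic import acorr_ljungbox
    rng = np.random.default_rng(0)
    for _ in range(20):
        r = rng.normal(size=int(rng.integers(30, 80)))
        h = 8
        Q, p = ljung_box(r, h)
        ref = acorr_ljungbox(r, lags=[h])
        assert Q == pytest.approx(float(ref["lb_stat"].iloc[0]), rel=1e-8)
        assert p == pytest.approx(float(ref["lb_pvalue"].iloc[0]), abs=1e-10)


def test_ljung_box_null_calibration():
    """At the procedure's lag rule, LB holds its nominal size at n=48."""
    rng = np.random.default_rng(1)
    h = StatsConfig.lb_lags(48)
    rej = sum(ljung_box(rng.normal(size=48), h)[1] < 0.05
              for _ in range(2000))
    assert 0.035 <= rej / 2000 <= 0.065


# ---- t test ------------------------------------------------------------

def test_t_symmetric_residuals():
    assert t_zero_mean(np.array([-1.0, 1.0, -1.0, 1.0])) == 1.0


def test_t_zero_variance_conventions():
    assert t_zero_mean(np.zeros(10)) == 1.0
    assert t_zero_mean(np.full(10, 0.5)) == 0.0


def test_t_power_at_half_sd_offset():
    rng = np.random.default_rng(2)
    rej = sum(t_zero_mean(rng.normal(0.5, 1.0, size=60)) < 0.05
              for _ in range(400))
    assert rej / 400 >= 0.9


# ---- Newey-West --------------------------------------------------------

def test_hac_zero_mean_gives_p_one():
    r = np.array([1.0, -1.0] * 10)
    assert newey_west_mean_p(r) == pytest.approx(1.0, abs=1e-12)


def test_hac_matches_statsmodels_sandwich():
    import statsmodels.api as sm
    rng = np.random.default_rng(3)
    for _ in range(10):
        r = ar1(rng, 80, 0.5)
        L = StatsConfig.hac_lag(len(r))
        fit = sm.OLS(r, np.ones(len(r))).fit(
            cov_type="HAC", cov_kwds={"maxlags": L, "use_correction": False})
        z_ref = float(fit.params[0] / fit.bse[0])
        p_ref = 2 * stats.norm.sf(abs(z_ref))
        assert newey_west_mean_p(r, prewhiten=False) == \
            pytest.approx(p_ref, abs=1e-8)


def test_hac_agrees_with_t_for_iid():
    """With iid residuals the weighted autocovariances are noise, so the
    HAC p-value tracks the plain t-test (typical agreement, large n)."""
    rng = np.random.default_rng(4)
    diffs = [abs(newey_west_mean_p(r) - t_zero_mean(r))
             for r in (rng.normal(size=200) for _ in range(200))]
    assert np.median(diffs) < 0.03
    assert np.quantile(diffs, 0.9) < 0.08


def test_hac_beats_naive_t_under_ar1():
    rng = np.random.default_rng(5)
    naive = hac = 0
    reps = 400
    for _ in range(reps):
        r = ar1(rng, 60, 0.6)
        naive += t_zero_mean(r) < 0.05
        hac += newey_west_mean_p(r) < 0.05
    assert naive / reps >= 0.10
    assert hac < naive


# ---- block bootstrap ---------------------------------------------------

def test_bootstrap_zero_residuals():
    assert block_bootstrap_mean_p(np.zeros(40), block_len=4) == 1.0


def test_bootstrap_seeded_reproducibility():
    rng = np.random.default_rng(6)
    r = rng.normal(size=60)
    p1 = block_bootstrap_mean_p(r, 4, B=500, seed=9)
    p2 = block_bootstrap_mean_p(r, 4, B=500, seed=9)
    assert p1 == p2


def test_bootstrap_block_length_errors():
    with pytest.raises(ValueError):
        block_bootstrap_mean_p(np.ones(10), block_len=10)
    with pytest.raises(ValueError):
        block_bootstrap_mean_p(np.arange(7.0), block_len=4)


def test_bootstrap_null_calibration():
    rng = np.random.default_rng(7)
    rej = 0
    reps = 300
    for i in range(reps):
        r = rng.normal(size=60)
        rej += block_bootstrap_mean_p(r, 4, B=1000, seed=i) < 0.05
    assert 0.02 <= rej / reps <= 0.09


# ---- composed procedure ------------------------------------------------

def test_conservative_combination_invariant():
    rng = np.random.default_rng(8)
    seen_auto = 0
    for i in range(100):
        r = ar1(rng, 60, 0.7)
        res = assess_gap_bias(r, StatsConfig(seed=i, bootstrap_B=500))
        if res.route == "autocorrelated":
            seen_auto += 1
            assert res.final_p >= res.hac_p - 1e-12
            assert res.final_p >= res.boot_p - 1e-12
            assert res.t_p is None
        else:
            assert res.hac_p is None and res.boot_p is None
    assert seen_auto >= 80           # strong AR(1) routes to the robust path


def test_degenerate_residuals_never_flagged_when_zero():
    res = assess_gap_bias(np.zeros(30), StatsConfig())
    assert res.degenerate and res.unbiased and res.route == "independent"
    res = assess_gap_bias(np.full(30, 0.3), StatsConfig())
    assert res.degenerate and not res.unbiased


def test_iid_residuals_mostly_independent_and_unbiased():
    rng = np.random.default_rng(9)
    indep = unbiased = 0
    reps = 300
    for i in range(reps):
        r = rng.normal(size=60)
        res = assess_gap_bias(r, StatsConfig(seed=i, bootstrap_B=500))
        indep += res.route == "independent"
        unbiased += res.unbiased
    assert indep / reps > 0.9
    assert 0.90 <= unbiased / reps <= 0.99


def test_power_monotone_in_offset():
    rng = np.random.default_rng(10)
    reps = 200
    rates = []
    noise = [rng.normal(size=60) for _ in range(reps)]   # common random numbers
    for offset in (0.0, 0.25, 0.5, 1.0):
        flagged = sum(
            not assess_gap_bias(noise[i] + offset,
                                StatsConfig(seed=i, bootstrap_B=500)).unbiased
            for i in range(reps))
        rates.append(flagged / reps)
    assert all(a <= b + 0.02 for a, b in zip(rates, rates[1:]))
    assert rates[-1] > 0.99


def test_summarize_bias_percentages():
    """42 unbiased gaps out of 46 report as 91.3% (one-decimal rounding)."""
    results = []
    for i in range(46):
        r = np.zeros(30) if i < 42 else np.full(30, 1.0)
        results.append(assess_gap_bias(r, StatsConfig(), gap_id=i, model="m"))
    summary = summarize_bias(results).iloc[0]
    assert summary["n_gaps"] == 46
    assert summary["n_unbiased"] == 42
    assert summary["pct_unbiased"] == 91.3


def test_summarize_bias_edge_cases():
    all_unbiased = [assess_gap_bias(np.zeros(30), StatsConfig(), i, "m")
                    for i in range(3)]
    assert summarize_bias(all_unbiased).iloc[0]["pct_unbiased"] == 100.0
    none_unbiased = [assess_gap_bias(np.full(30, 1.0), StatsConfig(), i, "m")
                     for i in range(3)]
    assert summarize_bias(none_unbiased).iloc[0]["pct_unbiased"] == 0.0
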