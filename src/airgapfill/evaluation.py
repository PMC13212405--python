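"""Per-gap accuracy metrics and their distributional comparison.

Each imputed gap is scored with MAE, RMSE and R² (baseline: the within-gap
observed mean, so a model that merely matches the local level scores 0 and
a model worse than that goes negative — which genuinely happens on short
noisy windows).  Distributions of the per-gap metrics across models are
compared with Shapiro–Wilk normality screening followed by the
Kruskal–Wallis omnibus test, Student-t 95% confidence intervals for the
metric means, and an ordinary-least-squares trend of RMSE against gap
duration (the error-vs-horizon growth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GapScore:
    gap_id: int
    model: str
    mae: float
    rmse: float
    r2: float                     # NaN when within-gap variance is zero
    duration_h: int


def score_gap(observed: np.ndarray, imputed: np.ndarray,
              gap_id: int = 0, model: str = "") -> GapScore:
    """MAE, RMSE and R² of one gap (R² baseline = within-gap observed mean)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(imputed, dtype=float)
    if len(o) != len(p) or len(o) < 2:
        raise ValueError("observed and imputed must share length >= 2")
    err = o - p
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = np.nan                # undefined: no within-gap variance
    else:
        r2 = 1.0 - float((err ** 2).sum()) / ss_tot
    return GapScore(gap_id, model, mae, rmse, r2, len(o))


def scores_frame(scores: list[GapScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores])


def metric_distribution(scores: pd.DataFrame,
                        metrics: tuple[str, ...] = ("mae", "rmse", "r2")
                        ) -> pd.DataFrame:
    """Median, quartiles and 1.5·IQR whiskers per model and metric.

    Quantiles use the linear-interpolation convention.  Whiskers are the
    most extreme data points within 1.5·IQR of the box edges (the usual
    box-plot rule).
    """
    rows = []
    for model, g in scores.groupby("model"):
        for metric in metrics:
            v = g[metric].dropna().to_numpy()
            if len(v) == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = v[(v >= lo_lim) & (v <= hi_lim)]
            rows.append({"model": model, "metric": metric, "n": len(v),
                         "median": med, "q1": q1, "q3": q3,
                         "whisker_lo": inside.min(), "whisker_hi": inside.max()})
    return pd.DataFrame(rows)


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk normality test (3 <= n <= 5000)."""
    v = np.asarray(values, dtype=float)
    if not (3 <= len(v) <= 5000):
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    group_sizes: list[int]


def kruskal_wallis(groups: list[np.ndarray]) -> KWResult:
    """Rank-based omnibus test (tie-corrected H, chi-square reference)."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups) or \
            sum(len(g) for g in groups) < 5:
        raise ValueError("need k >= 2 non-empty groups, total n >= 5")
    H, p = stats.kruskal(*groups)
    return KWResult(float(H), len(groups) - 1, float(p),
                    [len(g) for g in groups])


@dataclass
class CIResult:
    metric: str
    mean: float
    lower: float
    upper: float
    half_width: float
    level: float
    n: int


def mean_ci(values: np.ndarray, level: float = 0.95,
            metric: str = "", method: str = "t") -> CIResult:
    """Confidence interval for the mean: Student-t (default) or normal-z."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    m = float(v.mean())
    se = float(v.std(ddof=1) / np.sqrt(n))
    if method == "t":
        q = float(stats.t.ppf(0.5 + level / 2, df=n - 1))
    elif method == "z":
        q = float(stats.norm.ppf(0.5 + level / 2))
    else:
        raise ValueError("method must be 't' or 'z'")
    return CIResult(metric, m, m - q * se, m + q * se, q * se, level, n)


@dataclass
class TrendFit:
    slope: float                  # ppm per hour of gap duration
    intercept: float              # ppm
    n: int


def fit_rmse_trend(scores: pd.DataFrame, model: str | None = None,
                   metric: str = "rmse") -> TrendFit:
    """OLS of per-gap RMSE on gap duration (error growth with horizon)."""
    g = scores if model is None else scores[scores["model"] == model]
    x = g["duration_h"].to_numpy(dtype=float)
    y = g[metric].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct durations for a trend fit")
    slope, intercept = np.polyfit(x, y, 1)
    return TrendFit(float(slope), float(intercept), len(x))


def choose_comparison_route(groups: list[np.ndarray],
                            alpha: float = 0.05) -> str:
    """'nonparametric' when any Shapiro–Wilk p < alpha, else 'parametric'.

    Mirrors the study design: the omnibus comparison is Kruskal–Wallis
    whenever normality fails for any of the compared distributions.
    """
    for g in groups:
        if shapiro_wilk(g)[1] < alpha:
            return "nonparametric"
    return "parametric"
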