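"""End-to-end study orchestration.

``run_pipeline`` executes the full benchmark from one configuration:
simulate (or load) the station → census existing gaps → inject artificial
25–72 h test gaps → screen predictors and build supervised samples → train
the three model families → impute every artificial gap recursively →
score, compare distributions, fit error-vs-horizon trends → certify
residual bias → write all tables.

All randomness flows from one master seed: every stage draws its own
sub-seed from a spawned seed sequence, so runs are bit-reproducible and
adding a stage never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import census as census_mod
from . import evaluation as ev
from . import residual_bias as rb
from .features import (GBT_CO_LAGS, GBT_EXOG, Normalizer, build_lag_rows,
                       build_windows, ccf_table, select_predictors)
from .imputers import (GBTSpec, ImputationResult, NetSpec, TrainedImputer,
                       impute_gap, train_gbt, train_network,
                       write_imputations)
from .inject import ArtificialGapSet, InjectionPlan, gap_truth, \
    inject_artificial_gaps
from .series import StationSeries
from .synthetic import SyntheticConfig, generate_station, \
    inject_mechanism_gaps

log = logging.getLogger("airgapfill")

MODEL_FAMILIES = ("gbt", "lstm", "rnn")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Single source of truth for one benchmark run."""

    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    input_csv: str | None = None
    plan: InjectionPlan = field(default_factory=InjectionPlan)
    gbt: GBTSpec = field(default_factory=GBTSpec)
    lstm: NetSpec = field(default_factory=lambda: NetSpec(kind="lstm", epochs=8))
    rnn: NetSpec = field(default_factory=lambda: NetSpec(kind="rnn", epochs=8))
    stats: StatsConfigAlias = None  # type: ignore[valid-type]
    models: tuple[str, ...] = MODEL_FAMILIES
    net_predictors: tuple[str, ...] | None = None   # None -> CCF screening
    predictor_threshold: float = 0.2
    input_mode: str = "full_window"
    max_train_windows: int | None = 8000
    outdir: str | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.stats is None:
            self.stats = rb.StatsConfig()
        if (self.synthetic is None) == (self.input_csv is None):
            raise ValueError(
                "provide exactly one of a synthetic config or an input CSV")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = (SyntheticConfig(**raw["synthetic"])
                                   if raw["synthetic"] is not None else None)
        if raw.get("input_csv"):
            kwargs["input_csv"] = raw["input_csv"]
            kwargs.setdefault("synthetic", None)
        for key, klass in [("plan", InjectionPlan), ("gbt", GBTSpec),
                           ("lstm", NetSpec), ("rnn", NetSpec),
                           ("stats", rb.StatsConfig)]:
            if key in raw:
                kwargs[key] = klass(**raw[key])
        for key in ("models", "net_predictors", "predictor_threshold",
                    "input_mode", "max_train_windows", "outdir",
                    "master_seed"):
            if key in raw:
                kwargs[key] = (tuple(raw[key]) if key in
                               ("models", "net_predictors") and raw[key]
                               is not None else raw[key])
        return cls(**kwargs)


StatsConfigAlias = rb.StatsConfig


@dataclass
class RunReport:
    census: pd.DataFrame
    gap_manifest: pd.DataFrame
    ccf: pd.DataFrame
    predictors: list[str]
    scores: pd.DataFrame
    distribution: pd.DataFrame
    shapiro: pd.DataFrame
    kruskal: pd.DataFrame
    ci: pd.DataFrame
    trend: pd.DataFrame
    bias: pd.DataFrame
    bias_summary: pd.DataFrame
    imputations: list[ImputationResult]
    provenance: dict
    trained: dict = field(default_factory=dict, repr=False)
    gap_set: ArtificialGapSet | None = field(default=None, repr=False)
    series: StationSeries | None = field(default=None, repr=False)


def _sub_seeds(master: int, n: int) -> list[int]:
    """Deterministic child seeds, all below 2**31."""
    states = [int(ss.generate_state(1)[0]) % (2 ** 31)
              for ss in np.random.SeedSequence(master).spawn(n)]
    return states


def run_pipeline(config: RunConfig) -> RunReport:
    t_start = time.time()
    seeds = _sub_seeds(config.master_seed, 8)
    provenance = {"master_seed": config.master_seed, "stage_seeds": seeds,
                  "models": list(config.models)}

    # ---- stage 1: obtain the (gapped) station series --------------------
    stage = "simulate"
    try:
        if config.synthetic is not None:
            scfg = dataclasses.replace(config.synthetic, seed=seeds[0])
            complete = generate_station(scfg)
            gapped, _mech_truth = inject_mechanism_gaps(complete, scfg)
        else:
            gapped = StationSeries.from_csv(config.input_csv)
        log.info("stage=%s n_hours=%d seed=%d", stage, len(gapped), seeds[0])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 2: census of existing gaps -------------------------------
    stage = "census"
    try:
        gaps = census_mod.find_gaps(gapped, config.plan.target_variable)
        census = census_mod.bin_gaps(gaps)
        log.info("stage=%s n_gaps=%d", stage, len(gaps))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 3: artificial test gaps ----------------------------------
    stage = "inject"
    try:
        plan = dataclasses.replace(config.plan, seed=seeds[1])
        test_series, gap_set = inject_artificial_gaps(gapped, plan)
        log.info("stage=%s n_artificial=%d", stage, len(gap_set))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 4: predictor screening + samples -------------------------
    stage = "features"
    try:
        ccf = ccf_table(test_series, target=config.plan.target_variable)
        if config.net_predictors is not None:
            predictors = list(config.net_predictors)
        else:
            predictors = select_predictors(ccf, config.predictor_threshold)
        norm_vars = sorted(set(["CO"] + predictors + list(GBT_EXOG)))
        normalizer = Normalizer.fit(test_series, norm_vars)
        normalized = normalizer.apply(test_series)
        windows = build_windows(normalized, predictors, window=48,
                                exclusions=gap_set,
                                input_mode=config.input_mode)
        if config.max_train_windows and len(windows) > config.max_train_windows:
            rng = np.random.default_rng(seeds[2])
            keep = np.sort(rng.choice(len(windows), config.max_train_windows,
                                      replace=False))
            windows = dataclasses.replace(
                windows, X=windows.X[keep], y=windows.y[keep],
                t=windows.t[keep])
        lag_rows = build_lag_rows(normalized, exclusions=gap_set)
        log.info("stage=%s predictors=%s n_windows=%d n_lag_rows=%d",
                 stage, predictors, len(windows), len(lag_rows))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 5: training ----------------------------------------------
    stage = "train"
    try:
        trained: dict[str, TrainedImputer] = {}
        if "gbt" in config.models:
            trained["gbt"] = train_gbt(lag_rows, config.gbt, seeds[3],
                                       normalizer)
        if "lstm" in config.models:
            spec = dataclasses.replace(config.lstm, seed=seeds[4])
            trained["lstm"] = train_network(windows, spec, normalizer)
        if "rnn" in config.models:
            spec = dataclasses.replace(config.rnn, seed=seeds[5])
            trained["rnn"] = train_network(windows, spec, normalizer)
        log.info("stage=%s families=%s", stage, sorted(trained))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 6: recursive imputation ----------------------------------
    stage = "impute"
    try:
        imputations: list[ImputationResult] = []
        for gid, gap in enumerate(gap_set.gaps, start=1):
            for family, model in trained.items():
                imputations.append(impute_gap(model, test_series, gap,
                                              gap_id=gid))
        log.info("stage=%s n_results=%d", stage, len(imputations))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 7: evaluation --------------------------------------------
    stage = "evaluate"
    try:
        scores = []
        residuals: dict[tuple[int, str], np.ndarray] = {}
        for res in imputations:
            gap = gap_set.gaps[res.gap_id - 1]
            truth = gap_truth(gap_set, gap)
            obs = truth.to_numpy()
            imp = res.values.to_numpy()
            scores.append(ev.score_gap(obs, imp, res.gap_id, res.family))
            residuals[(res.gap_id, res.family)] = obs - imp
        scores_df = ev.scores_frame(scores)
        if len(scores_df):
            distribution = ev.metric_distribution(scores_df)
            shapiro_rows, ci_rows, kw_rows, trend_rows = [], [], [], []
            for metric in ("mae", "rmse", "r2"):
                groups, names = [], []
                for family in sorted(trained):
                    v = scores_df.loc[scores_df["model"] == family, metric] \
                        .dropna().to_numpy()
                    if len(v) >= 3:
                        W, p = ev.shapiro_wilk(v)
                        shapiro_rows.append({"model": family, "metric": metric,
                                             "W": W, "p": p})
                    if len(v) >= 2:
                        ci = ev.mean_ci(v, metric=metric)
                        ci_rows.append({"model": family, "metric": metric,
                                        "mean": ci.mean, "lower": ci.lower,
                                        "upper": ci.upper,
                                        "half_width": ci.half_width,
                                        "n": ci.n})
                        groups.append(v)
                        names.append(family)
                if len(groups) >= 2 and sum(map(len, groups)) >= 5:
                    kw = ev.kruskal_wallis(groups)
                    kw_rows.append({"metric": metric, "H": kw.H, "df": kw.df,
                                    "p": kw.p,
                                    "groups": "/".join(names)})
            for family in sorted(trained):
                sub = scores_df[scores_df["model"] == family]
                if sub["duration_h"].nunique() >= 2:
                    tr = ev.fit_rmse_trend(scores_df, model=family)
                    trend_rows.append({"model": family, "slope": tr.slope,
                                       "intercept": tr.intercept, "n": tr.n})
            shapiro_df = pd.DataFrame(shapiro_rows)
            kw_df = pd.DataFrame(kw_rows)
            ci_df = pd.DataFrame(ci_rows)
            trend_df = pd.DataFrame(trend_rows)
        else:
            distribution = pd.DataFrame()
            shapiro_df = kw_df = ci_df = trend_df = pd.DataFrame()
        log.info("stage=%s n_scores=%d", stage, len(scores_df))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage 8: residual-bias certification ---------------------------
    stage = "bias"
    try:
        bias_results = []
        bias_seeds = _sub_seeds(seeds[6], max(len(imputations), 1))
        for res, bseed in zip(imputations, bias_seeds):
            cfg = dataclasses.replace(config.stats, seed=bseed)
            r = residuals[(res.gap_id, res.family)]
            bias_results.append(rb.assess_gap_bias(r, cfg, res.gap_id,
                                                   res.family))
        bias_df = rb.results_frame(bias_results) if bias_results else \
            pd.DataFrame()
        bias_summary = rb.summarize_bias(bias_results)
        log.info("stage=%s n_bias=%d", stage, len(bias_results))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    provenance["runtime_s"] = round(time.time() - t_start, 2)
    provenance["n_windows"] = len(windows)
    provenance["n_lag_rows"] = len(lag_rows)
    manifest = pd.DataFrame({
        "gap_id": range(1, len(gap_set.gaps) + 1),
        "start": [g.start for g in gap_set.gaps],
        "end": [g.end for g in gap_set.gaps],
        "duration_h": [g.duration_h for g in gap_set.gaps]})
    report = RunReport(census, manifest, ccf, predictors, scores_df,
                       distribution, shapiro_df, kw_df, ci_df, trend_df,
                       bias_df, bias_summary, imputations, provenance,
                       trained=trained, gap_set=gap_set, series=test_series)
    if config.outdir:
        write_report(report, config.outdir)
    return report


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write every report table as delimited text plus a JSON summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "census.csv": report.census,
        "artificial_gaps.csv": report.gap_manifest,
        "ccf.csv": report.ccf.rename_axis("variable").reset_index(),
        "scores.csv": report.scores,
        "distribution.csv": report.distribution,
        "shapiro.csv": report.shapiro,
        "kruskal.csv": report.kruskal,
        "ci.csv": report.ci,
        "trend.csv": report.trend,
        "bias.csv": report.bias,
        "bias_summary.csv": report.bias_summary,
    }
    for name, frame in tables.items():
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)
    write_imputations(report.imputations, out / "imputations.csv")
    written.append(out / "imputations.csv")
    summary = {
        "provenance": report.provenance,
        "predictors": report.predictors,
        "n_artificial_gaps": int(len(report.gap_manifest)),
        "median_metrics": {
            f"{row['model']}_{row['metric']}": row["median"]
            for _, row in report.distribution.iterrows()
        } if len(report.distribution) else {},
        "pct_unbiased": {
            row["model"]: row["pct_unbiased"]
            for _, row in report.bias_summary.iterrows()
        } if len(report.bias_summary) else {},
    }
    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, default=str))
    written.append(spath)
    return written
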