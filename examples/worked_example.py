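"""Minimal end-to-end run: one year of synthetic data, 10 test gaps."""
from airgapfill import (InjectionPlan, NetSpec, RunConfig, SyntheticConfig,
                        run_pipeline)

config = RunConfig(
    synthetic=SyntheticConfig(n_hours=8760, seed=0),   # 1 year, hourly
    plan=InjectionPlan(n_gaps=10),                     # 25-72 h CO gaps
    lstm=NetSpec(kind="lstm", epochs=4),
    rnn=NetSpec(kind="rnn", epochs=4),
    max_train_windows=3000,
    master_seed=7)

report = run_pipeline(config)
print("selected predictors:", report.predictors)
print(report.scores.groupby("model")[["mae", "rmse", "r2"]]
      .median().round(4))
print(report.bias_summary.to_string(index=False))
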