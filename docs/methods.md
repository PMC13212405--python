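# Methods

This note records the modelling choices behind `airgapfill`: what each
stage assumes, which knobs matter, and what the synthetic benchmark does
and does not demonstrate.

## Synthetic station model

The generator produces the minimal structure the imputation task needs;
it is not a chemistry model.

CO (ppm) is

```
CO(t) = b + A1·cos(2π(h−13)/24) + A2·cos(2π(h−7)/12) + w·cos(2πt/168) + e(t)
e(t) = φ·e(t−1) + ε(t),   ε ~ N(0, σ²)
```

with h the hour of day.  The 12-hour harmonic phased at 07:00 produces
the double rush-hour peak typical of kerbside CO; the 24-hour harmonic
deepens the overnight trough; the weekly term is weak.  Defaults:
b = 0.6 ppm, A = (0.12, 0.22) ppm, w = 0.05 ppm, φ = 0.6, σ = 0.08 ppm —
levels chosen so the diurnal swing dominates the stochastic part, as it
does for a traffic-driven primary pollutant, while leaving enough noise
that imputation is non-trivial.

Each coupled channel is `base + gain·(CO signal − b) + own noise`, with
positive gains for the nitrogen oxides (co-emission), a negative gain for
O₃ (titration by fresh NO), and near-zero gains for SO₂/PM.  Temperature
is a single diurnal harmonic peaking mid-afternoon; relative humidity is
in anti-phase, clipped to [0, 100] %.  Pollutant channels are clipped at
zero.  Every channel draws from its own PRNG stream spawned from the
master seed, so adding a channel never changes another channel's values.

Mechanism gaps mask whole contiguous runs per channel.  Run lengths come
from a four-bin distribution (1–24, 25–72, 73–120, 121–168 h; within-bin
uniform) defaulting to 90 / 7 / 3 / 0 % — sub-day outages dominate, as in
real station logs.  Under MCAR, start hours are uniform; under MAR
(default) the start probability is logistic in the z-score of an observed
covariate (relative humidity by default, strength 1.5), and never depends
on the masked value itself.

**What passing tests do not show.**  The generator is stationary apart
from its periodic terms; real series have trends, regime changes
(roadworks, sensor drift), heavy-tailed spikes and cross-channel
missingness correlation.  Model rankings and unbiased-gap percentages
obtained here characterise the pipeline's correctness and calibration,
not expected field performance.

## Artificial test gaps

Gaps are cut only from the CO channel: integer lengths uniform on
[25, 72] h, start positions uniform over feasible placements, rejection
sampling with a bounded retry budget.  Feasibility requires (i) a fully
observed gap body — all channels when `require_complete_exog` is set
(default), since the models consume the exogenous trajectory inside the
gap; (ii) no overlap with mechanism gaps, other artificial gaps, *or any
other gap's warm-up buffer*; (iii) a complete 48 h warm-up window before
the gap so every model has a full input at the first imputed hour.
Infeasible plans fail loudly, reporting how many gaps were placed.

Sequential rejection sampling is not exactly uniform over valid
gap-set tuples, but it is simple, seeded-reproducible, and empirically
uniform in length (chi-square checked in the test suite).

## Features and samples

Predictor screening first-differences every channel (removing the shared
seasonal drift that would produce spurious correlations) and computes the
Pearson cross-correlation of each candidate against differenced CO at
lags 0–25 h, pairwise-complete, requiring ≥ 30 joint observations per
lag.  Channels whose peak |r| clears 0.2 are kept, ordered by that peak
(ties alphabetical); the set can be overridden per model in the run
configuration.  On the synthetic station the selected set is the nitrogen
oxides, O₃ and PM — the gain-coupled channels — matching the physical
expectation that contemporaneous co-emitted species carry most of the
signal.

Normalization is per-variable z-scoring with the sample (n−1) standard
deviation, estimated on the training span; predictions are inverted back
to ppm before any reporting.

Two supervised representations are built (only from hours whose full
input block and target are observed, and never from hours inside
artificial gaps):

* 48 h multivariate windows → target CO(t), for the networks.  The
  default feeds the full 48 h history of CO and each selected exogenous
  channel; an alternative mode (`exog_now`) feeds the CO window with the
  exogenous values at t held constant, for the reading of the task in
  which exogenous inputs are strictly contemporaneous.  Both modes are
  implemented and tested; `full_window` is the default because it strictly
  dominates in information content.
* explicit lag rows (CO at t−12/−24/−36/−48 plus NO₂, NO, TEMP, RH at t)
  → target CO(t), for the trees.  The 12-hour lag spacing spans two full
  diurnal cycles, which is what lets a memoryless learner capture the
  daily seasonality.

## Models and recursive imputation

* GBT: 600 trees, depth 6, learning rate 0.05, squared-error loss
  (xgboost, single-threaded, seeded).
* LSTM 64/32 recurrent units + 64 ReLU dense + linear scalar; RNN 128/64
  sigmoid recurrent units + 128 ReLU dense + linear scalar.  Both are
  implemented in numpy (forward + exact backpropagation through time,
  verified against central finite differences to ~1e-8 relative error)
  and trained with minibatch Adam (lr 1e-3, batch 64) on MSE, with early
  stopping on a 10 % validation split (patience 5).  Epoch defaults: 30
  for standalone use; the pipeline default is 8 epochs with early
  stopping, and the shipped benchmark configurations use 4 — on the
  synthetic station the validation loss plateaus within a few epochs, so
  longer schedules buy nothing.

Imputation is chronological and recursive: each filled hour is written
into the working CO series and used by subsequent lag features / windows.
Hours whose CO inputs were themselves imputed are flagged (for a gap
longer than 12 h every hour after the twelfth is necessarily flagged for
the GBT).  Exogenous values inside artificial gaps are read from the
observed series — they were never masked; if a mechanism gap removes an
exogenous value, the last observation is carried forward and the hour is
flagged, with a warning.  The GBT cannot fill a multi-day gap from
measured lags alone (every lag eventually falls inside the gap), so
feeding imputed values back is the only scheme consistent with full-gap
imputation; the flags keep the provenance auditable.

## Evaluation

Per gap: MAE, RMSE (ppm) and R² = 1 − Σ(o−p)²/Σ(o−ō)² with ō the
within-gap observed mean.  The local-mean baseline is deliberate: a
global-mean baseline would credit a model for merely tracking seasonality
and could not produce the negative R² values that short, locally flat
gaps legitimately yield.  Zero within-gap variance makes R² undefined and
is reported as such.

Across gaps: medians/quartiles with linear-interpolation quantiles and
1.5·IQR whiskers; Shapiro–Wilk normality screening, with the omnibus
comparison made by Kruskal–Wallis (tie-corrected, chi-square reference)
whenever any compared distribution fails normality — which per-gap error
distributions essentially always do; Student-t 95 % confidence intervals
for metric means (normal-z available); and an OLS trend of RMSE on gap
duration for the error-vs-horizon growth.

## Bias certification

Residuals r(t) = observed − imputed per gap.  Routing and tests:

* Ljung-Box with h = max(1, min(5, ⌊n/10⌋)) lags.  The lag count is kept
  small deliberately: with h near 10 the chi-square reference over-rejects
  at gap-sized samples (measured ~7 % at nominal 5 %, n = 48), which would
  inflate the routing false-alarm rate; h ≤ 5 restores nominal size while
  leaving power against AR(1) dependence of φ ≥ 0.6 essentially at 100 %.
* Independent route: two-sided one-sample t.  Zero-variance conventions:
  constant-zero residuals give p = 1 (a perfect imputation is never
  flagged), constant non-zero give p = 0.
* Autocorrelated route: (a) Newey–West z-test with Bartlett truncation
  L = ⌊4(n/100)^{2/9}⌋ and AR(1) prewhitening (Andrews–Monahan, the
  default of R's `sandwich::NeweyWest`).  Prewhitening matters at these
  sample sizes: the demeaned empirical autocovariances sum to zero by
  construction, so the raw kernel estimate understates the long-run
  variance of short, strongly autocorrelated residual series no matter
  the truncation, inflating false alarms well above nominal.  The raw
  estimator remains available (`prewhiten=False`) and is cross-checked
  against statsmodels.  The normal reference is the default; a t
  (n−1 df) reference is available.  (b) Moving-block bootstrap with block
  length b = max(2, ⌈n^{1/3}⌉), B = 2000 resamples of ⌈n/b⌉ uniformly
  drawn overlapping blocks truncated to n, centered two-sided p with the
  add-one correction.  Final p = max of the two; unbiased ⇔ p ≥ 0.05.

Measured operating characteristics (Monte Carlo, recomputed by the test
suite and `scripts/acceptance.py`): type-I error ≈ 5–6 % on iid residuals
of gap-typical lengths; ≥ 95 % power against a 0.5·sd mean offset at
n = 60; under zero-mean AR(1) φ = 0.6 the robust route engages ~95 % of
the time and the conservative decision flags ~10 % (the naive t flags
~31 %).

## Pipeline determinism and problem sizes

All stage seeds spawn deterministically from one master seed; xgboost and
the numpy networks are single-threaded, so two runs with the same
configuration produce identical score, bias and census tables (audited by
a test).  The shipped benchmark uses a 2-year station, 46 artificial
gaps, networks trained on ≤ 4000 windows for 4 epochs — sizes chosen so a
full benchmark completes in a few minutes on one CPU while every
qualitative conclusion (model ranking, calibration, routing behaviour) is
already stable at that scale.

## Known limitations

* The networks are trained one-step-ahead but evaluated multi-step; no
  scheduled sampling or multi-step loss is implemented, so their rollout
  error compounds by design.
* Exogenous channels inside gaps are assumed available; joint outages of
  CO and all predictors would force last-observation-carried-forward
  inputs and degrade accordingly.
* The HAC test uses an asymptotic reference at n as small as 25; the
  conservative max-p combination with the bootstrap is what keeps the
  composed procedure near nominal size there.
* No multiple-testing correction is applied across gaps; the unbiased-gap
  percentage is a per-gap error rate, not a family-wise statement.
* Censusing is per channel; correlated cross-channel outages are not
  summarised jointly.
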