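# Methods

`stepdyn` implements an idiographic (within-person) analysis of daily step
counts in four stages: preparation of per-participant daily series, detection
of sudden behavioral gains and losses, computation of dynamic complexity as
an early-warning signal, and a discrete-time event-history model linking
local dynamic complexity to the hazard of a subsequent gain or loss.  A
synthetic cohort generator with known ground truth makes every stage testable
without access to real wearable data.

## Data model and preparation

A participant's record is a dense daily grid: every calendar day between the
first and last observation is present, with unobserved days stored as
explicit missing values.  Day indices are 1-based from the participant's
first study day.

Preparation applies, in order:

1. **Wear-time validity** — days with fewer than 600 minutes of device wear
   are treated as not observed.  Series without a wear channel (all synthetic
   data) skip this step with a warning.
2. **Inclusion** — a participant enters the analysis set iff the series spans
   at least 90 days and strictly less than 20% of days are missing.
3. **Imputation** — missing days are filled with the Kalman-smoothed state of
   a local-level structural model (random walk + observation noise) fitted to
   the observed days by maximum likelihood, clipped at zero steps.  The
   local-level form is the smallest state-space model consistent with
   ARIMA-family Kalman imputation and keeps the step deterministic; if the
   likelihood optimisation fails the fallback is linear interpolation with a
   logged warning.  Observed values are never altered.  In testing against an
   exact Kalman smoother run at the true parameters of AR(1)-structured
   series, the fitted local-level imputation's RMSE is within 10% of that
   oracle's.

The order validity → inclusion → imputation means the missingness fraction is
judged after wear-invalid days are removed; each step is idempotent on its
own output.

## Sudden gains and losses

Each imputed series is segmented by CART-style recursive binary partitioning
with the day index as the only predictor.  Because the predictor is 1-D and
ordered, the best split of a node is found exactly (prefix-sum SSE over all
admissible cut days; earliest day wins ties).  A split is accepted only if

- both children span at least `min_segment_days` (default 7, the stability
  criterion), and
- the SSE reduction is at least `complexity_parameter` (default 0.01) times
  the **root** SSE — the canonical complexity-pruning rule of the rpart
  family.

Segment levels are the segment means of the observed values (regression trees
predict means).  An adjacent-segment shift is classified as a sudden gain
(level up) or loss (level down) iff its absolute size reaches
`threshold_frac` (default 0.30; 0.20/0.40 in sensitivity runs) times the
participant's median daily steps over the full imputed study period.  The
median rather than the mean scales the criterion because individual daily
step distributions are right-skewed.  The event day is the first day of the
new regime.

One guard supplements the structural stability rule: a **transient
excursion** — a segment of exactly the minimum admissible length whose level
departs from and reverts to its surroundings (flanking levels agreeing to
within half the smaller bounding shift) — contributes no events from either
of its bounding shifts.  Without this, a multi-day spike wide enough to
survive mean-dilution inside a minimum-length segment would register as a
spurious gain/loss pair despite never producing a stable new state.  The
excursion test depends only on the segmentation, never on the threshold, so
event sets at thresholds 0.40 ⊆ 0.30 ⊆ 0.20 for a fixed segmentation.

Known operating characteristics: greedy top-down splitting with the
root-relative acceptance rule preferentially misses shifts bounded by short
regimes on long series (their SSE contribution is small relative to the root)
and localises split days only to within a few days under heavy noise.  The
recovery tests therefore measure precision/recall on well-separated regimes
(≥ 21 days, shift-to-noise calibrated so identifiability holds: lognormal
sigma 0.15, shifts ≥ 1.5× threshold, ±2-day matching), where both exceed
0.9; under the descriptive-default noise (sigma 0.25) recovery is
substantially lower.  That gap is a property of the segmentation algorithm,
not of its implementation — the implementation is verified exactly against
an exhaustive best-split oracle.

## Dynamic complexity

For each day *n* with a full backward window (default `window_days = 7`
points ending at day *n*), two statistics are computed on a fixed
per-participant scale `[scale_min, scale_max]` (defaults: observed min/max of
the imputed series — the idiographic attainable range):

- **Fluctuation intensity F**: the window is decomposed into maximal monotone
  runs (a direction reversal or a zero first-difference ends a run); run *k*
  with amplitude *a_k* over *d_k* day-intervals contributes *a_k/d_k*, and
  F = Σ_k (a_k/d_k) / (s·(m−1)) with *s* the scale range and *m* the window
  length.  F = 1 exactly for every-day alternation between the scale bounds.
- **Distribution measure D**: the sorted window is compared with perfectly
  uniform coverage of the scale; for every index pair (i, i+c) only the
  shortfall of the empirical spread below the uniform spread c·s/(m−1)
  counts, and D = 1 − (total shortfall)/(total uniform spread).  D = 0 for a
  constant window, D = 1 for exactly uniform spacing.

Both statistics are invariant to joint linear rescaling of data and bounds
and to time reversal of the window; C = F·D ∈ [0, 1] is the dynamic
complexity score.  Days before the first full window are undefined (NaN),
never zero.  **Local dynamic complexity** (LDC) for day *n* is the maximum C
over the `ldc_lag_days` days strictly preceding *n* (default 3; 2 and 4 in
sensitivity runs), so LDC(lag 4) ≥ LDC(lag 3) ≥ LDC(lag 2) pointwise.

Two convention points are deliberate and config-exposed: the "window between
day n−7 and day n" is realised as the 7 points n−6…n (window length equals
`window_days` exactly), and ties (zero first-differences) are excluded from
monotone runs.  Complexity is computed on imputed series, matching the
pipeline order in which imputation precedes all analysis.

## Event-history model

Each participant contributes one record per day with a defined LDC (days
before the window+lag warm-up are excluded — the only exclusion).  The
binary outcome marks a classified event that day; `time` is the study day;
`duration` is a 1-based inter-event clock (1 on study day 1 and on the day
after any event).  The clock resets on *any* event regardless of which
outcome a model later uses, so the three model variants share one at-risk
process.  Censored participants (no events) contribute all-zero outcome rows.

The hazard model is a mixed-effects logistic regression

    outcome ~ time + duration + ldc + (1 + time + duration + ldc || participant)

with a random intercept and mutually uncorrelated random slopes (diagonal
random-effects covariance).  Three variants are fitted: both outcomes
pooled, gains only, and losses only; the single-direction variants keep only
participants with at least one event of that direction.  Continuous
predictors are z-scored over the included records of each variant (grand
standardization — one "per 1 SD" effect per model), so odds ratios are per
1 SD.

Estimation is maximum likelihood under the Laplace approximation, written
in-package in the style of lme4's default GLMM scheme: for candidate
random-effect scales, the fixed effects and per-group random-effect modes
are found jointly by penalized IRLS (Newton steps on the joint penalized
likelihood, solved group-by-group via Schur complement, with step halving),
and the Laplace deviance is minimised over the scales by Nelder-Mead from a
fixed start (all scales 0.3, fixed tolerances), making fits deterministic.
A scale estimated below 1e-4 is singular: it is pinned to zero, the
remaining scales are re-optimised, and the dropped slope is recorded on the
fit.  The fitter is cross-checked in the test suite against lme4's `glmer`
(via Rscript) on seeded data — fixed effects agree to < 0.06, random-effect
SDs to < 0.05, and −2·logLik to < 2 — and against a plain logistic fit in
the zero-heterogeneity limit.

95% confidence intervals are likelihood-profile by default: the profiled
deviance (other fixed effects and random-effect modes re-optimised) is
bisected at the χ²(1) cutoff.  Random-effect scales are held at their MLE
during profiling; re-optimising them at every profile point is prohibitively
slow and changes near-quadratic intervals negligibly (the suite verifies
profile and Wald intervals agree within 5% at large n).  Any coefficient
whose profile cannot be bracketed falls back to its Wald interval and is
flagged per-coefficient in the output.

## Synthetic cohort generator

The generator emulates a ~151-person wearable cohort observed for about
seven months.  Per participant:

- **Length**: normal around 226 days (sd 18% of the mean), clipped to
  [107, 320].
- **Base level**: normal (9800, 2500) steps/day, floored at 1500.  The base
  mean is set so that, after the weekend factor and lognormal noise mean,
  cohort mean daily steps land near 9700.
- **Regimes**: piecewise-constant levels; regime durations are
  `min_regime_length` (default 10) plus geometric extras, with the expected
  count tied to `regime_change_rate` (default 0.9 shifts per 30 days ≈ 6 per
  series).  Transition magnitudes are ±U(0.30, 0.60) × base level, applied
  additively with reflection at bounds symmetric around the base level — a
  multiplicative ±frac walk would drift downward systematically.
  Transitions are instantaneous level shifts, matching the sudden-gain/loss
  construct (no ramps).
- **Daily counts**: level × weekend factor (0.85 on Sat/Sun — a plausible
  magnitude for the known weekday/weekend difference) × multiplicative
  lognormal noise (sigma 0.25; a negative-binomial option exists), rounded
  to non-negative integers.  An optional AR(1) coefficient on the log-noise
  (default 0) exists because no within-regime autocorrelation value is
  available to anchor it.
- **Early-warning precursors**: during the 5 days before each transition the
  noise scale is multiplied by a direction-specific factor — default 2.0
  before losses and 1.0 before gains, encoding the loss-specific
  pre-transition instability that the analysis is designed to detect.  Set
  both to 1.0 for precursor-free cohorts.
- **Missingness**: each participant's missing fraction is exponential with
  mean 0.09, capped at 0.27; missing days arrive in geometric-length runs
  (mean 2.5) to mimic multi-day device-off gaps.  Exactly
  `round(fraction × n_days)` days are masked; the pre-masking series is kept
  in the ground truth for imputation scoring.

Per-participant seeds are spawned deterministically from the cohort seed, so
identical configs give bitwise-identical cohorts.  With defaults, Monte-Carlo
means over seeded replicates give ≈ 9680 steps/day, ≈ 6.2 transitions per
participant, and mean length ≈ 226 days; about 85% of generated participants
survive the 20%-missing inclusion rule.

What the generator does **not** emulate: intraday (minute-level) structure
and wear-time channels, seasonal/weather trends, intervention-arm effects,
gradual ramps between states, and heavy-tailed single-day outliers (the
observed single-day maximum in real cohorts far exceeds what lognormal noise
around the level produces).  Passing tests on this cohort therefore
demonstrate correctness and calibration of the pipeline's machinery under
the stated generative assumptions, not that real walking behavior satisfies
those assumptions.

## Numerical and design choices

- Tie-breaks: the earliest day wins among equal-SSE splits; determinism
  everywhere given config + seed (no unseeded draws).
- Degenerate inputs: constant series → one segment, zero events, F = D = 0;
  a degenerate complexity scale (max = min) gives F = D = 0 by convention;
  series shorter than two minimum segments segment as a single piece with a
  warning; all-missing series cannot be imputed (error).
- Problem sizes in the test suite are chosen to keep the full run in a few
  minutes: detection recovery uses 3 × 30 participants, model recovery 50
  replicates of 50 participants × 200 days, and the end-to-end
  loss-precursor experiment 10 replicates of 30 participants.
- The event-history `k` (records per model) is governed solely by the
  warm-up exclusion; analyses of real cohorts that applied additional
  exclusions will have smaller `k` for the same participants.

## Known limitations

- The regression tree is greedy: it is exactly the classical CART recursion
  (verified against exhaustive per-node search), not globally optimal
  partitioning, and inherits CART's short-regime blindness and split-day
  localisation noise described above.
- Profile CIs condition on the estimated random-effect scales; coverage
  statements in the suite are Monte-Carlo, not exact.
- The local-level imputation model is intentionally minimal; strongly
  autocorrelated or trending gaps may be imputed better by richer ARIMA
  state-space forms.
- Single-indicator complexity only: F and D are computed from steps alone,
  and no alternative early-warning statistics (lag-1 autocorrelation,
  variance ratios) are provided.
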