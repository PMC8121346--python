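# stepdyn

Idiographic analysis of daily step-count time series: detection of **sudden
behavioral gains and losses**, **dynamic complexity** as an early-warning
signal, and a **discrete-time event-history model** linking the two.

Physical-activity interventions are usually evaluated from a few short
snapshots of behavior, which hides how walking actually changes day to day.
When a person's daily step count is observed for months, changes often look
discontinuous: stretches of stable behavior separated by abrupt shifts to a
higher or lower level.  Complex-systems theory predicts that such state
transitions are preceded by *critical fluctuations* — a measurable rise in
the irregularity of the signal — which opens the door to just-in-time
interventions triggered shortly *before* a loss of activity.  `stepdyn` is a
tested, reusable pipeline for that analysis, aimed at researchers working
with wearable-derived daily step counts (and at method developers, via its
fully synthetic, ground-truthed cohort generator).

## The method

For each participant with daily steps $y_1,\dots,y_T$ (missing days imputed
by a Kalman smoother under a local-level state-space model):

1. **Sudden gains/losses.** A CART regression tree partitions $y_t$ on the
   day index $t$ into piecewise-constant regimes, each at least 7 days long
   (stability criterion).  An adjacent-regime shift is a *sudden gain*
   (*loss*) iff

   $$|\bar y_{\text{post}} - \bar y_{\text{pre}}| \ge \theta \cdot \mathrm{median}(y_{1:T}),$$

   with $\theta = 0.30$ in the main analysis (0.20/0.40 in sensitivity
   runs).  For a median of 7000 steps/day the cut is 2100 steps/day.

2. **Dynamic complexity.** On a backward 7-day window ending at each day,
   the fluctuation intensity $F \in [0,1]$ (amplitude × frequency of
   direction changes) and distribution measure $D \in [0,1]$ (evenness of
   coverage of the participant's attainable range) give the complexity score
   $C = F \cdot D$.  The *local dynamic complexity* for day $n$ is
   $\mathrm{LDC}_n = \max(C_{n-3}, C_{n-2}, C_{n-1})$ (lags 2 and 4 in
   sensitivity runs).

3. **Event-history model.** On the person-day grid, the hazard of an event
   is modelled with a mixed-effects logistic regression (Laplace ML,
   uncorrelated random slopes, fitted by an in-package PIRLS/Laplace
   routine cross-checked against lme4):

   `event ~ time + duration + LDC + (1 + time + duration + LDC || participant)`

   where `time` is the study day and `duration` the days since the previous
   event (censoring/repeated-event control).  Predictors are z-scored, so
   odds ratios are per 1 SD, with 95% likelihood-profile CIs.  The model is
   fitted for both outcomes pooled, gains only, and losses only.

See `docs/methods.md` for assumptions, parameter defaults, numerical
conventions, and what the synthetic generator does and does not emulate.

## Worked example

```python
from stepdyn import CohortConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(cohort=CohortConfig(n_participants=25),
                     ci_method="profile", seed=42)
res = run_pipeline(cfg)
```

With this seed the pipeline simulates 25 participants (about seven months of
daily steps each, with missing days, weekend effects, and variance inflation
in the five days before each sudden loss), imputes, detects events, computes
complexity traces, and fits the three hazard models.  Printing the summary
and the LDC rows of the odds-ratio tables gives:

```
participants: 23
mean series length: 241.2 d  (range (168, 320))
mean daily steps:   10491
events: 141 (76 gains / 65 losses), 6.13 per participant
mean |level change|: 5080 steps; mean inter-event gap: 29.6 d
both         LDC OR 1.20  95% CI [1.04, 1.37]  (N=23, k=5341)
gains_only   LDC OR 0.50  95% CI [0.31, 0.73]  (N=22, k=5078)
losses_only  LDC OR 1.62  95% CI [1.40, 1.84]  (N=21, k=4956)
```

Two of the 25 simulated participants fail the inclusion rule (≥ 90 days,
< 20% missing) and are dropped.  Participants average ~6 sudden gains/losses
about a month apart.  Because the generator inflates pre-loss variance only,
a 1-SD increase in local dynamic complexity raises the odds of a sudden loss
in the next days by ~62% (OR 1.62, CI excluding 1) while gains show no
positive association — the early-warning signature the pipeline is built to
detect.  `N` is the participants entering each model (single-direction
models keep only participants with that event type) and `k` the person-day
records.

The same analysis runs from the shell on any long-format CSV
(`participant_id, date, steps[, wear_minutes]`):

```bash
stepdyn simulate --out sim/ --seed 42          # or bring your own CSV
stepdyn prepare  --in sim/cohort.csv --out prep/
stepdyn run      --config pipeline.yaml        # full pipeline + artifacts
stepdyn sensitivity --config pipeline.yaml     # 3 thresholds x 3 lags x 3 outcomes
```

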