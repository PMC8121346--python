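"""Discrete-time event-history analysis of sudden gains and losses.

Each participant contributes one record per study day with a defined local
dynamic complexity (LDC) value; the binary outcome marks whether a
classified gain/loss occurs that day.  The hazard is modelled with a
mixed-effects logistic regression

    outcome ~ time + duration + LDC + (1 + time + duration + LDC || participant)

with a random intercept and mutually uncorrelated random slopes.  ``time``
(study day) controls for calendar trends in event risk; ``duration`` (days
since the previous event, or since study start) handles censored
participants and repeated events.  Continuous predictors are z-scored over
the included records, so odds ratios are per 1 SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complexity import ComplexityParams, ComplexityTrace
from .detection import TransitionEvent
from .mixed_logit import MixedLogitModel

logger = logging.getLogger("stepdyn")

PREDICTORS = ("time", "duration", "ldc")


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome is modelled and how.

    ``gains_only`` / ``losses_only`` restrict both the outcome coding and the
    sample: only participants who experienced at least one event of that
    direction are kept.  ``ci_method`` selects likelihood-profile (default)
    or Wald intervals.
    """

    outcome_filter: str = "both"  # both | gains_only | losses_only
    ci_method: str = "profile"  # profile | wald
    random_slopes: bool = True

    def __post_init__(self) -> None:
        if self.outcome_filter not in ("both", "gains_only", "losses_only"):
            raise ValueError(f"unknown outcome_filter {self.outcome_filter!r}")
        if self.ci_method not in ("profile", "wald"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")


@dataclass
class ModelFit:
    """Fitted hazard model with odds ratios per 1-SD predictor change."""

    outcome_filter: str
    coefficients: dict[str, float]  # log-odds scale, standardized predictors
    odds_ratios: pd.DataFrame  # index: predictor; columns: OR, ci_low, ci_high
    re_sd: dict[str, float]
    n_participants: int
    n_records: int
    n_events: int
    converged: bool
    ci_method: str
    scaling: dict[str, tuple[float, float]]  # predictor -> (mean, sd)
    dropped_random_effects: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def build_event_table(
    events: list[TransitionEvent],
    traces: dict[str, ComplexityTrace],
    params: ComplexityParams = ComplexityParams(),
) -> pd.DataFrame:
    """One record per participant-day with a defined LDC value.

    Columns: ``participant_id, day, outcome, is_gain, is_loss, time,
    duration, ldc``.  ``duration`` is a 1-based inter-event clock: 1 on study
    day 1 and on the day after any event, increasing by 1 per day otherwise;
    it resets on *any* event regardless of the outcome later modelled, so the
    three models share one at-risk clock.  Participants without events
    (censored) contribute all-zero outcome rows.  Days whose LDC is
    undefined (the window + lag warm-up) are excluded — the only exclusion
    applied.
    """
    by_pid: dict[str, list[TransitionEvent]] = {}
    for ev in events:
        by_pid.setdefault(ev.participant_id, []).append(ev)

    frames = []
    for pid, trace in traces.items():
        n = trace.n_days
        pid_events = sorted(by_pid.get(pid, []), key=lambda e: e.day)
        for ev in pid_events:
            if not 1 <= ev.day <= n:
                raise ValueError(
                    f"{pid}: event day {ev.day} outside series range 1..{n}"
                )
        gain_days = {e.day for e in pid_events if e.direction == "gain"}
        loss_days = {e.day for e in pid_events if e.direction == "loss"}
        event_days = sorted(gain_days | loss_days)

        days = np.arange(1, n + 1)
        duration = np.empty(n, dtype=int)
        last = 0  # day of the most recent prior event; 0 = study start
        ev_iter = iter(event_days)
        nxt = next(ev_iter, None)
        for d in days:
            duration[d - 1] = d - last
            if nxt is not None and d == nxt:
                last = d
                nxt = next(ev_iter, None)
        ldc = trace.ldc(params.ldc_lag_days)
        df = pd.DataFrame(
            {
                "participant_id": pid,
                "day": days,
                "outcome": np.isin(days, event_days).astype(int),
                "is_gain": np.isin(days, sorted(gain_days)).astype(int),
                "is_loss": np.isin(days, sorted(loss_days)).astype(int),
                "time": days,
                "duration": duration,
                "ldc": ldc,
            }
        )
        frames.append(df[~np.isnan(ldc)])
    table = pd.concat(frames, ignore_index=True)
    logger.info(
        "event table: %d records, %d participants, %d events",
        len(table), table["participant_id"].nunique(), int(table["outcome"].sum()),
    )
    return table


def standardize_predictors(
    records: pd.DataFrame, columns: tuple[str, ...] = PREDICTORS
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score predictors over all included records (grand standardization).

    Returns the transformed copy and ``{column: (mean, sd)}`` for
    back-transformation to the raw scale.
    """
    out = records.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for col in columns:
        mean = float(out[col].mean())
        sd = float(out[col].std(ddof=1))
        if not sd > 0:
            raise ValueError(f"predictor {col!r} has zero variance; cannot standardize")
        out[col] = (out[col] - mean) / sd
        scaling[col] = (mean, sd)
    return out, scaling


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _subset_for_outcome(records: pd.DataFrame, outcome_filter: str) -> pd.DataFrame:
    """Outcome coding and participant subsetting for one model variant."""
    df = records.copy()
    if outcome_filter == "both":
        df["y"] = df["outcome"]
        return df
    col = "is_gain" if outcome_filter == "gains_only" else "is_loss"
    had = df.groupby("participant_id")[col].transform("max") > 0
    df = df[had].copy()
    df["y"] = df[col]
    return df


def fit_event_model(records: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> ModelFit:
    """Fit the discrete-time hazard model for one outcome variant.

    Subsets participants per ``spec.outcome_filter``, z-scores the predictors
    over the subset, and fits the mixed logistic model by Laplace ML.  A
    singular random-slope scale is pinned to zero and noted in
    ``dropped_random_effects``.
    """
    df = _subset_for_outcome(records, spec.outcome_filter)
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants after subsetting")
    if df["y"].nunique() < 2:
        raise ValueError("outcome contains a single class after subsetting")
    df, scaling = standardize_predictors(df)

    names = ["intercept", *PREDICTORS]
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in PREDICTORS])
    re_cols = list(range(X.shape[1])) if spec.random_slopes else [0]
    model = MixedLogitModel(
        X, df["y"].to_numpy(), df["participant_id"].to_numpy(),
        re_cols=re_cols, fe_names=names,
    )
    fit = model.fit()

    or_table = compute_odds_ratios(fit, method=spec.ci_method)
    return ModelFit(
        outcome_filter=spec.outcome_filter,
        coefficients=dict(zip(fit.fe_names, fit.beta)),
        odds_ratios=or_table,
        re_sd=dict(zip(fit.re_names, fit.re_sd)),
        n_participants=fit.n_groups,
        n_records=fit.n_obs,
        n_events=int(df["y"].sum()),
        converged=fit.converged,
        ci_method=spec.ci_method,
        scaling=scaling,
        dropped_random_effects=list(fit.dropped_re),
    )


def compute_odds_ratios(fit, method: str = "profile") -> pd.DataFrame:
    """Odds ratios exp(beta) with 95% CIs for a mixed logistic fit.

    ``method='profile'`` bisects the profiled deviance at the chi-square(1)
    95% cutoff; any coefficient whose profile cannot be bracketed falls back
    to its Wald interval (flagged in the ``ci_method`` column).
    """
    if method == "profile":
        bounds, methods = fit.profile_ci()
    elif method == "wald":
        bounds = fit.wald_ci()
        methods = ["wald"] * len(fit.beta)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return pd.DataFrame(
        {
            "OR": np.exp(fit.beta),
            "ci_low": np.exp(bounds[:, 0]),
            "ci_high": np.exp(bounds[:, 1]),
            "ci_method": methods,
        },
        index=pd.Index(fit.fe_names, name="predictor"),
    )
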