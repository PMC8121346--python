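"""End-to-end orchestration: prepare -> detect -> complexity -> model.

`run_pipeline` executes the full idiographic analysis on either a long-format
CSV or a freshly simulated synthetic cohort, producing a cohort summary,
per-participant segmentations/events/complexity traces, and the three hazard
models (both outcomes, gains only, losses only).  `run_sensitivity_grid`
repeats the analysis over the 3 x 3 x 3 grid of event thresholds
(20/30/40% of the median), LDC lags (2/3/4 days) and outcome variants.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .complexity import ComplexityParams, ComplexityTrace, complexity_trace
from .data_io import InclusionReport, StepSeries
from .detection import DetectionParams, RegimeSegmentation, TransitionEvent, detect
from .event_history import ModelFit, ModelSpec, build_event_table, fit_event_model
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger("stepdyn")

SENSITIVITY_THRESHOLDS = (0.20, 0.30, 0.40)
SENSITIVITY_LAGS = (2, 3, 4)
OUTCOME_FILTERS = ("both", "gains_only", "losses_only")


@dataclass
class PipelineConfig:
    """Everything one run needs; ``input_csv`` xor ``cohort`` selects the source."""

    input_csv: str | Path | None = None
    cohort: CohortConfig | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    complexity: ComplexityParams = field(default_factory=ComplexityParams)
    ci_method: str = "profile"
    min_wear_minutes: int = data_io.DEFAULT_MIN_WEAR_MINUTES
    min_days: int = data_io.DEFAULT_MIN_DAYS
    max_missing_frac: float = data_io.DEFAULT_MAX_MISSING_FRAC
    out_dir: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.cohort is None):
            raise ValueError("exactly one of input_csv or cohort must be given")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ValueError(f"input_csv does not exist: {self.input_csv}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs and kwargs["cohort"] is not None:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "detection" in kwargs:
            kwargs["detection"] = DetectionParams(**kwargs["detection"])
        if "complexity" in kwargs:
            kwargs["complexity"] = ComplexityParams(**kwargs["complexity"])
        return cls(**kwargs)


@dataclass
class CohortSummary:
    """Descriptive statistics of one analysed cohort."""

    n_participants: int
    mean_series_length: float
    series_length_range: tuple[int, int]
    mean_missing_days: float
    missing_days_range: tuple[int, int]
    mean_daily_steps: float
    median_daily_steps: float
    daily_steps_range: tuple[float, float]
    n_events: int
    n_gains: int
    n_losses: int
    events_per_participant_mean: float
    events_per_participant_range: tuple[int, int]
    mean_abs_delta_steps: float
    mean_abs_delta_gains: float
    mean_abs_delta_losses: float
    mean_inter_event_days: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    summary: CohortSummary
    inclusion: list[InclusionReport]
    prepared: list[StepSeries]
    segmentations: dict[str, RegimeSegmentation]
    events: list[TransitionEvent]
    traces: dict[str, ComplexityTrace]
    event_table: pd.DataFrame | None
    fits: dict[str, ModelFit]


def summarize_cohort(
    prepared: list[StepSeries], events: list[TransitionEvent]
) -> CohortSummary:
    lengths = np.array([s.n_days for s in prepared])
    missing = np.array([int(s.imputed_mask.sum()) for s in prepared])
    per_series_mean = np.array([s.steps.mean() for s in prepared])
    all_steps = np.concatenate([s.steps for s in prepared])

    ev_counts = {s.participant_id: 0 for s in prepared}
    gaps: list[int] = []
    by_pid: dict[str, list[int]] = {}
    for ev in events:
        ev_counts[ev.participant_id] += 1
        by_pid.setdefault(ev.participant_id, []).append(ev.day)
    for days in by_pid.values():
        days = sorted(days)
        gaps.extend(b - a for a, b in zip(days, days[1:]))

    deltas = np.array([abs(ev.delta_steps) for ev in events])
    gains = np.array([abs(ev.delta_steps) for ev in events if ev.direction == "gain"])
    losses = np.array([abs(ev.delta_steps) for ev in events if ev.direction == "loss"])
    counts = np.array(list(ev_counts.values()))
    return CohortSummary(
        n_participants=len(prepared),
        mean_series_length=float(lengths.mean()),
        series_length_range=(int(lengths.min()), int(lengths.max())),
        mean_missing_days=float(missing.mean()),
        missing_days_range=(int(missing.min()), int(missing.max())),
        mean_daily_steps=float(per_series_mean.mean()),
        median_daily_steps=float(np.median(all_steps)),
        daily_steps_range=(float(all_steps.min()), float(all_steps.max())),
        n_events=len(events),
        n_gains=sum(1 for e in events if e.direction == "gain"),
        n_losses=sum(1 for e in events if e.direction == "loss"),
        events_per_participant_mean=float(counts.mean()),
        events_per_participant_range=(int(counts.min()), int(counts.max())),
        mean_abs_delta_steps=float(deltas.mean()) if deltas.size else 0.0,
        mean_abs_delta_gains=float(gains.mean()) if gains.size else 0.0,
        mean_abs_delta_losses=float(losses.mean()) if losses.size else 0.0,
        mean_inter_event_days=float(np.mean(gaps)) if gaps else float("nan"),
    )


def _load_input(config: PipelineConfig) -> list[StepSeries]:
    if config.input_csv is not None:
        return data_io.read_step_series(config.input_csv)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    return [series for series, _ in generate_cohort(cohort_cfg)]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; writes artifacts when ``out_dir`` is set.

    Stages: read/simulate -> wear validity -> inclusion -> Kalman imputation
    -> regression-tree segmentation + gain/loss classification -> dynamic
    complexity traces -> event-history models (both / gains only / losses
    only).  If no events are detected the model stage is skipped with an
    explicit notice.  Fully deterministic given the config.
    """
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    raw = _load_input(config)
    logger.info("stage prepare: %d raw series", len(raw))

    prepared: list[StepSeries] = []
    reports: list[InclusionReport] = []
    for series in raw:
        cooked, report = data_io.prepare_series(
            series, config.min_wear_minutes, config.min_days, config.max_missing_frac
        )
        reports.append(report)
        if cooked is not None:
            prepared.append(cooked)
    n_excluded = len(raw) - len(prepared)
    if n_excluded:
        logger.info("stage prepare: %d participant(s) excluded", n_excluded)
    if not prepared:
        raise RuntimeError("prepare stage: no participants pass the inclusion criteria")

    segmentations: dict[str, RegimeSegmentation] = {}
    events: list[TransitionEvent] = []
    for series in prepared:
        seg, evs = detect(series, config.detection)
        segmentations[series.participant_id] = seg
        events.extend(evs)
    logger.info("stage detect: %d events across %d participants",
                len(events), len(prepared))

    traces = {
        s.participant_id: complexity_trace(s, config.complexity) for s in prepared
    }

    summary = summarize_cohort(prepared, events)

    fits: dict[str, ModelFit] = {}
    event_table = None
    if not events:
        logger.warning("no events detected; model stage skipped")
    else:
        event_table = build_event_table(events, traces, config.complexity)
        for outcome in OUTCOME_FILTERS:
            try:
                fits[outcome] = fit_event_model(
                    event_table,
                    ModelSpec(outcome_filter=outcome, ci_method=config.ci_method),
                )
            except ValueError as exc:
                logger.warning("model %r skipped: %s", outcome, exc)

    result = PipelineResult(
        summary=summary,
        inclusion=reports,
        prepared=prepared,
        segmentations=segmentations,
        events=events,
        traces=traces,
        event_table=event_table,
        fits=fits,
    )
    if config.out_dir is not None:
        _write_artifacts(result, config)
    return result


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def events_to_frame(events: list[TransitionEvent],
                    prepared: list[StepSeries] | None = None) -> pd.DataFrame:
    start_dates = {s.participant_id: s.start_date for s in prepared or []}
    rows = []
    for ev in events:
        row = dataclasses.asdict(ev)
        start = start_dates.get(ev.participant_id)
        row["date"] = (
            str(start + pd.Timedelta(days=ev.day - 1).to_pytimedelta())
            if start is not None
            else ""
        )
        rows.append(row)
    cols = ["participant_id", "day", "date", "direction", "pre_level",
            "post_level", "delta_steps", "delta_frac"]
    return pd.DataFrame(rows, columns=cols if rows else cols)


def traces_to_frame(traces: dict[str, ComplexityTrace],
                    lags: tuple[int, ...] = SENSITIVITY_LAGS) -> pd.DataFrame:
    frames = []
    for pid, tr in traces.items():
        df = pd.DataFrame(
            {"participant_id": pid, "day": np.arange(1, tr.n_days + 1),
             "F": tr.F, "D": tr.D, "C": tr.C}
        )
        for lag in lags:
            df[f"LDC_lag{lag}"] = tr.ldc(lag)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def model_report(fits: dict[str, ModelFit]) -> dict:
    """Table-shaped JSON report: per outcome, OR and CI per predictor."""
    report: dict = {}
    for outcome, fit in fits.items():
        ors = fit.odds_ratios
        report[outcome] = {
            "n_participants": fit.n_participants,
            "n_records": fit.n_records,
            "n_events": fit.n_events,
            "converged": fit.converged,
            "ci_method": fit.ci_method,
            "dropped_random_effects": fit.dropped_random_effects,
            "predictors": {
                name: {
                    "OR": float(ors.loc[name, "OR"]),
                    "ci_low": float(ors.loc[name, "ci_low"]),
                    "ci_high": float(ors.loc[name, "ci_high"]),
                    "ci_method": str(ors.loc[name, "ci_method"]),
                }
                for name in ors.index
            },
            "random_effect_sd": {k: float(v) for k, v in fit.re_sd.items()},
        }
    return report


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_io.write_step_series(result.prepared, out / "prepared.csv")
    data_io.write_inclusion_reports(result.inclusion, out / "inclusion.csv")
    events_to_frame(result.events, result.prepared).to_csv(
        out / "events.csv", index=False
    )
    traces_to_frame(result.traces).to_csv(out / "complexity.csv", index=False)
    seg_rows = []
    for pid, seg in result.segmentations.items():
        for (a, b), lv in zip(seg.segment_spans, seg.segment_levels):
            seg_rows.append({"participant_id": pid, "start_day": a,
                             "end_day": b, "level": lv})
    pd.DataFrame(seg_rows).to_csv(out / "segments.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary.to_dict(), fh, indent=2)
    with open(out / "models.json", "w") as fh:
        json.dump(model_report(result.fits), fh, indent=2)
    with open(out / "run_config.json", "w") as fh:
        json.dump(_config_dict(config), fh, indent=2, default=str)
    logger.info("artifacts written to %s", out)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


# ---------------------------------------------------------------------------
# Sensitivity grid
# ---------------------------------------------------------------------------

def run_sensitivity_grid(
    config: PipelineConfig,
    thresholds: tuple[float, ...] = SENSITIVITY_THRESHOLDS,
    lags: tuple[int, ...] = SENSITIVITY_LAGS,
) -> pd.DataFrame:
    """Event counts and LDC odds ratios over the threshold x lag x outcome grid.

    The regression-tree segmentation and the complexity traces do not depend
    on the event threshold or the LDC lag, so they are computed once;
    classification is redone per threshold and the LDC column per lag.
    Per-cell model failures are recorded in the ``error`` column and the grid
    completes.
    """
    from .complexity import ComplexityParams as _CP
    from .detection import classify_transitions

    base = dataclasses.replace(config, out_dir=None)
    raw = _load_input(base)
    prepared = []
    for series in raw:
        cooked, _ = data_io.prepare_series(
            series, base.min_wear_minutes, base.min_days, base.max_missing_frac
        )
        if cooked is not None:
            prepared.append(cooked)
    segs = {s.participant_id: detect(s, base.detection)[0] for s in prepared}
    medians = {s.participant_id: float(np.median(s.steps)) for s in prepared}
    traces = {s.participant_id: complexity_trace(s, base.complexity) for s in prepared}

    rows = []
    for thr in thresholds:
        det = dataclasses.replace(base.detection, threshold_frac=thr)
        events: list[TransitionEvent] = []
        for pid, seg in segs.items():
            events.extend(classify_transitions(seg, medians[pid], det, pid))
        n_gain = sum(1 for e in events if e.direction == "gain")
        n_loss = len(events) - n_gain
        for lag in lags:
            cparams = _CP(
                window_days=base.complexity.window_days,
                ldc_lag_days=lag,
                scale_min=base.complexity.scale_min,
                scale_max=base.complexity.scale_max,
            )
            table = build_event_table(events, traces, cparams) if events else None
            for outcome in OUTCOME_FILTERS:
                row = {
                    "threshold": thr,
                    "lag": lag,
                    "outcome": outcome,
                    "n_events": len(events),
                    "n_gains": n_gain,
                    "n_losses": n_loss,
                    "ldc_or": np.nan,
                    "ldc_ci_low": np.nan,
                    "ldc_ci_high": np.nan,
                    "error": "",
                }
                if table is None:
                    row["error"] = "no events"
                else:
                    try:
                        fit = fit_event_model(
                            table,
                            ModelSpec(outcome_filter=outcome, ci_method=base.ci_method),
                        )
                        row["ldc_or"] = float(fit.odds_ratios.loc["ldc", "OR"])
                        row["ldc_ci_low"] = float(fit.odds_ratios.loc["ldc", "ci_low"])
                        row["ldc_ci_high"] = float(fit.odds_ratios.loc["ldc", "ci_high"])
                    except Exception as exc:  # noqa: BLE001 - grid must complete
                        row["error"] = str(exc)
                rows.append(row)
    grid = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid.to_csv(out / "sensitivity_grid.csv", index=False)
    return grid
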