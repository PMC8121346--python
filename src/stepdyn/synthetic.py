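"""Synthetic cohort generator with known ground-truth regimes and precursors.

Generates per-participant daily step series as piecewise-stable regimes with
instantaneous level shifts, multiplicative right-skewed daily noise, a
weekend/weekday level difference, optional variance inflation in the days
immediately preceding a shift (an early-warning precursor), and missing days
with gap-like run structure.

Default parameters emulate the descriptive statistics of a ~151-person
wearable cohort observed for about seven months: mean series length 226 days
(range 107-320), ~9700 steps/day on average, roughly six level shifts per
participant with mean inter-shift gaps around a month, and ~20 missing days
per participant (range 0-61).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .data_io import StepSeries

_BASE_START_DATE = _dt.date(2019, 6, 1)
# keep regime levels physiologically plausible for daily step counts
_LEVEL_FLOOR = 1500.0
_LEVEL_CEIL = 30000.0


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults reproduce the emulated cohort.

    ``regime_change_rate`` is the expected number of level shifts per 30 days
    of observation; ``transition_magnitude_frac`` bounds the fractional level
    shift drawn uniformly per transition; the precursor multipliers inflate
    the daily noise scale during the ``precursor_window`` days before a shift
    of the corresponding direction (1.0 disables the precursor).
    """

    n_participants: int = 151
    series_length_dist: tuple[float, int, int] = (226.0, 107, 320)  # mean, min, max days
    base_level_dist: tuple[float, float] = (9800.0, 2500.0)  # mean, sd steps/day
    regime_change_rate: float = 0.9  # expected transitions per 30 days
    transition_magnitude_frac: tuple[float, float] = (0.30, 0.60)
    min_regime_length: int = 10
    weekday_effect_frac: float = 0.85  # multiplicative weekend level factor
    noise_model: str = "lognormal"  # or "negative-binomial"
    noise_dispersion: float = 0.25  # lognormal sigma, or negbin size if negbin
    precursor_window: int = 5
    precursor_sd_multiplier_loss: float = 2.0
    precursor_sd_multiplier_gain: float = 1.0
    missing_frac_dist: tuple[float, float] = (0.09, 0.27)  # mean fraction, max
    ar1_coefficient: float = 0.0  # within-regime AR(1) on the log-noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        mean_len, lo, hi = self.series_length_dist
        if not (1 <= lo <= mean_len <= hi):
            raise ValueError("series_length_dist must satisfy min <= mean <= max")
        if self.base_level_dist[0] <= 0 or self.base_level_dist[1] < 0:
            raise ValueError("base level mean must be > 0 and sd >= 0")
        if self.regime_change_rate < 0:
            raise ValueError("regime_change_rate must be >= 0")
        flo, fhi = self.transition_magnitude_frac
        if not (0 < flo <= fhi <= 1):
            raise ValueError("transition_magnitude_frac must lie in (0, 1]")
        if self.min_regime_length < 1:
            raise ValueError("min_regime_length must be >= 1")
        if not 0 < self.weekday_effect_frac <= 2:
            raise ValueError("weekday_effect_frac must be positive")
        if self.noise_model not in ("lognormal", "negative-binomial"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        if self.precursor_window < 0:
            raise ValueError("precursor_window must be >= 0")
        if min(self.precursor_sd_multiplier_loss, self.precursor_sd_multiplier_gain) < 0:
            raise ValueError("precursor multipliers must be >= 0")
        mfrac, mmax = self.missing_frac_dist
        if not (0 <= mfrac <= mmax < 1):
            raise ValueError("missing_frac_dist must satisfy 0 <= mean <= max < 1")
        if not -1 < self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in (-1, 1)")


@dataclass
class GroundTruth:
    """Truth record emitted alongside each synthetic series.

    ``true_breakpoints`` are 1-based day indices of the first day of each new
    regime; ``complete_steps`` holds the pre-masking values so imputation can
    be scored against them.
    """

    true_breakpoints: list[int]
    true_directions: list[str]  # 'gain' | 'loss', parallel to breakpoints
    true_levels: list[float]  # steps/day per regime, len = len(breakpoints) + 1
    precursor_days: set[int] = field(default_factory=set)
    complete_steps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.true_levels) != len(self.true_breakpoints) + 1:
            raise ValueError("need exactly one more level than breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(self.true_breakpoints, self.true_breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        for lv1, lv2 in zip(self.true_levels, self.true_levels[1:]):
            if lv1 == lv2:
                raise ValueError("consecutive regimes must differ in level")


def _draw_series_length(config: CohortConfig, rng: np.random.Generator) -> int:
    mean_len, lo, hi = config.series_length_dist
    if lo == hi:
        return int(lo)
    length = rng.normal(mean_len, 0.18 * mean_len)
    return int(np.clip(round(length), lo, hi))


def _draw_regime_plan(
    config: CohortConfig,
    n_days: int,
    rng: np.random.Generator,
    forced_transitions: list[tuple[int, str, float]] | None,
) -> tuple[list[int], list[float], list[str]]:
    """Breakpoints (1-based first day of new regime), levels, directions."""
    base = max(rng.normal(*config.base_level_dist), _LEVEL_FLOOR)

    if forced_transitions is not None:
        breakpoints = [int(d) for d, _, _ in forced_transitions]
        levels = [base]
        directions = []
        for _, direction, frac in forced_transitions:
            sign = 1.0 if direction == "gain" else -1.0
            levels.append(levels[-1] * (1.0 + sign * frac))
            directions.append(direction)
        return breakpoints, levels, directions
    # random plan: shifts are +- frac x base level (additive, drift-free walk)

    if config.regime_change_rate <= 0:
        return [], [base], []

    mean_regime = 30.0 / config.regime_change_rate
    if config.min_regime_length * max(n_days / mean_regime, 1.0) > n_days:
        raise ValueError(
            "min_regime_length x expected regime count exceeds the series length; "
            "lower regime_change_rate or min_regime_length"
        )
    mean_extra = max(mean_regime - config.min_regime_length, 1.0)
    p_geom = 1.0 / (1.0 + mean_extra)

    breakpoints: list[int] = []
    day = 0
    while True:
        duration = config.min_regime_length + int(rng.geometric(p_geom)) - 1
        day += duration
        if day + config.min_regime_length > n_days:
            break
        breakpoints.append(day + 1)  # 1-based first day of the new regime

    flo, fhi = config.transition_magnitude_frac
    levels = [base]
    directions: list[str] = []
    # plausibility bounds symmetric around the base level, so reflections do
    # not impart drift to the level walk
    lo_bound = max(_LEVEL_FLOOR, 0.25 * base)
    hi_bound = min(_LEVEL_CEIL, 2.0 * base - lo_bound)
    for _ in breakpoints:
        delta = rng.uniform(flo, fhi) * base
        sign = 1.0 if rng.random() < 0.5 else -1.0
        new = levels[-1] + sign * delta
        if not lo_bound <= new <= hi_bound:  # bounce off plausibility bounds
            sign = -sign
            new = levels[-1] + sign * delta
        levels.append(new)
        directions.append("gain" if sign > 0 else "loss")
    return breakpoints, levels, directions


def generate_series(
    config: CohortConfig,
    participant_seed: int,
    n_days: int | None = None,
    forced_transitions: list[tuple[int, str, float]] | None = None,
    participant_id: str = "SYN",
) -> tuple[StepSeries, GroundTruth]:
    """Generate one complete (no missing days) series plus its ground truth.

    ``forced_transitions`` pins breakpoints exactly: a list of
    ``(day, direction, magnitude_frac)`` with 1-based days, overriding the
    random regime plan (used by tests that need shifts at known positions).
    Deterministic given ``(config, participant_seed)``.
    """
    rng = np.random.default_rng(participant_seed)
    if n_days is None:
        n_days = _draw_series_length(config, rng)
    breakpoints, levels, directions = _draw_regime_plan(
        config, n_days, rng, forced_transitions
    )

    day_level = np.empty(n_days)
    bounds = [0] + [b - 1 for b in breakpoints] + [n_days]
    for lv, (a, b) in zip(levels, zip(bounds, bounds[1:])):
        day_level[a:b] = lv

    # direction-specific noise-scale multiplier on the precursor days
    sd_mult = np.ones(n_days)
    precursor_days: set[int] = set()
    for bp, direction in zip(breakpoints, directions):
        mult = (
            config.precursor_sd_multiplier_gain
            if direction == "gain"
            else config.precursor_sd_multiplier_loss
        )
        lo = max(bp - 1 - config.precursor_window, 0)
        sd_mult[lo : bp - 1] = mult
        precursor_days.update(range(lo + 1, bp))

    start_date = _BASE_START_DATE + _dt.timedelta(days=int(rng.integers(0, 7)))
    dow = (np.arange(n_days) + start_date.weekday()) % 7
    weekday_factor = np.where(dow >= 5, config.weekday_effect_frac, 1.0)

    mean_per_day = day_level * weekday_factor
    if config.noise_model == "lognormal":
        sigma = config.noise_dispersion * sd_mult
        z = rng.standard_normal(n_days)
        if config.ar1_coefficient != 0.0:
            phi = config.ar1_coefficient
            z = np.asarray(
                [z[0]] + list(z[1:]), dtype=float
            )  # innovations; filter below
            for t in range(1, n_days):
                z[t] = phi * z[t - 1] + np.sqrt(1 - phi**2) * z[t]
        steps = mean_per_day * np.exp(sigma * z)
    else:  # negative-binomial: variance = m + m^2/size; precursor shrinks size
        size = config.noise_dispersion / np.maximum(sd_mult, 1e-12) ** 2
        if config.noise_dispersion == 0:
            steps = mean_per_day.copy()
        else:
            p = size / (size + np.maximum(mean_per_day, 1e-9))
            steps = rng.negative_binomial(size, p).astype(float)

    steps = np.maximum(np.round(steps), 0.0)
    series = StepSeries(participant_id=participant_id, start_date=start_date, steps=steps)
    truth = GroundTruth(
        true_breakpoints=list(breakpoints),
        true_directions=list(directions),
        true_levels=[float(lv) for lv in levels],
        precursor_days=precursor_days,
        complete_steps=steps.copy(),
    )
    return series, truth


def inject_missingness(
    series: StepSeries,
    fraction: float,
    rng: np.random.Generator | int,
    mean_run_length: float = 2.5,
) -> StepSeries:
    """Mask exactly ``round(fraction * n_days)`` days as missing.

    Missing days arrive in runs with geometric lengths (mean
    ``mean_run_length``) to mimic multi-day device-off gaps rather than
    isolated holes.  The input series is left untouched, so its values remain
    available for imputation scoring.
    """
    if not 0 <= fraction < 1:
        raise ValueError("missing fraction must lie in [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = series.copy()
    n = out.n_days
    target = int(round(fraction * n))
    if target == 0:
        return out
    p_geom = 1.0 / max(mean_run_length, 1.0)
    missing = np.zeros(n, dtype=bool)
    while missing.sum() < target:
        start = int(rng.integers(0, n))
        run = int(rng.geometric(p_geom))
        stop = min(start + run, n)
        room = target - int(missing.sum())
        idx = np.flatnonzero(~missing[start:stop])[:room] + start
        missing[idx] = True
    out.steps[missing] = np.nan
    return out


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[StepSeries, GroundTruth]]:
    """Generate ``n_participants`` independent series with missing days.

    Per-participant seeds are spawned deterministically from ``config.seed``,
    so identical configs give bitwise-identical cohorts.  Each participant's
    missing fraction is drawn from a truncated distribution with the
    configured mean and cap; complete values are kept in the ground truth.
    """
    cohort: list[tuple[StepSeries, GroundTruth]] = []
    for i in range(config.n_participants):
        ss = np.random.SeedSequence([config.seed, i])
        child_seed = int(ss.generate_state(1)[0])
        series, truth = generate_series(
            config, child_seed, participant_id=f"P{i + 1:03d}"
        )
        mfrac_mean, mfrac_max = config.missing_frac_dist
        rng = np.random.default_rng(child_seed + 1)
        if mfrac_mean > 0:
            # exponential with the target mean, truncated at the cap
            frac = float(np.clip(rng.exponential(mfrac_mean), 0.0, mfrac_max))
            series = inject_missingness(series, frac, rng)
        cohort.append((series, truth))
    return cohort


def write_ground_truth(cohort: list[tuple[StepSeries, GroundTruth]], path) -> None:
    """Sidecar CSV of true transitions: one row per breakpoint."""
    import pandas as pd

    rows = []
    for series, truth in cohort:
        for k, bp in enumerate(truth.true_breakpoints):
            rows.append(
                {
                    "participant_id": series.participant_id,
                    "breakpoint_day": bp,
                    "direction": truth.true_directions[k],
                    "pre_level": truth.true_levels[k],
                    "post_level": truth.true_levels[k + 1],
                }
            )
    pd.DataFrame(
        rows,
        columns=["participant_id", "breakpoint_day", "direction", "pre_level", "post_level"],
    ).to_csv(path, index=False)
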