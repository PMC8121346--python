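"""Dynamic complexity: fluctuation intensity F, distribution measure D, C = F*D.

Both statistics are computed on a backward moving window (default 7 days)
ending at each day, on a fixed per-participant scale [scale_min, scale_max].
F captures how large and how frequent direction changes are, reaching 1 for
a window alternating between the scale extremes every day.  D captures how
evenly the window's values cover the attainable range, reaching 1 when the
sorted values are exactly uniformly spaced across it.  Their product C is the
per-day dynamic complexity score; the early-warning predictor "local dynamic
complexity" (LDC) for day n is the maximum C over the ``ldc_lag_days`` days
strictly preceding n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import StepSeries

logger = logging.getLogger("stepdyn")


@dataclass(frozen=True)
class ComplexityParams:
    """Window and lag settings for the complexity trace.

    ``window_days`` points ending at day n form the backward window for day n
    (first defined day = ``window_days``); ``ldc_lag_days`` is the length of
    the strictly-preceding span maximised over for LDC (3 main analysis,
    2 and 4 in sensitivity runs).  ``scale_min``/``scale_max`` fix the
    attainable range; when None they default to the participant's observed
    min/max over the full imputed series.
    """

    window_days: int = 7
    ldc_lag_days: int = 3
    scale_min: float | None = None
    scale_max: float | None = None

    def __post_init__(self) -> None:
        if self.window_days < 2:
            raise ValueError("window_days must be >= 2")
        if self.ldc_lag_days < 1:
            raise ValueError("ldc_lag_days must be >= 1")
        if (
            self.scale_min is not None
            and self.scale_max is not None
            and not self.scale_max > self.scale_min
        ):
            raise ValueError("scale_max must exceed scale_min")


@dataclass
class ComplexityTrace:
    """Per-day F, D and C = F*D for one participant.

    Arrays are aligned with the series (index 0 = study day 1); days before
    ``defined_from`` (1-based) hold NaN — they are undefined, not zero.
    """

    participant_id: str
    F: np.ndarray
    D: np.ndarray
    C: np.ndarray
    defined_from: int

    @property
    def n_days(self) -> int:
        return int(self.C.size)

    def ldc(self, lag_days: int) -> np.ndarray:
        """Local dynamic complexity per day: max C over the preceding ``lag_days``.

        LDC for day n (1-based) is ``max(C[n-lag], ..., C[n-1])``, strictly
        excluding day n itself; NaN where any required C is undefined.
        """
        n = self.n_days
        out = np.full(n, np.nan)
        first = self.defined_from + lag_days  # earliest day with a full lag span
        for day in range(first, n + 1):
            out[day - 1] = self.C[day - 1 - lag_days : day - 1].max()
        return out


def _run_decomposition(window: np.ndarray) -> list[tuple[float, int]]:
    """Maximal monotone runs of a window as (amplitude, n_intervals) pairs.

    Runs are delimited by direction reversals; a zero first-difference
    terminates the current run and forms its own zero-amplitude run (ties are
    not part of a trend).
    """
    diffs = np.diff(window)
    runs: list[tuple[float, int]] = []
    k = 0
    while k < diffs.size:
        d = diffs[k]
        if d == 0:
            runs.append((0.0, 1))
            k += 1
            continue
        j = k
        while j + 1 < diffs.size and np.sign(diffs[j + 1]) == np.sign(d):
            j += 1
        runs.append((float(abs(window[j + 1] - window[k])), j + 1 - k))
        k = j + 1
    return runs


def fluctuation_intensity(
    window: np.ndarray, scale_min: float, scale_max: float
) -> float:
    """Fluctuation intensity F in [0, 1] of one backward window.

    The window is decomposed into maximal monotone runs; run k with amplitude
    a_k over d_k day-intervals contributes a_k / d_k, and the sum is
    normalised by the maximum attainable value s * (m - 1) (every-day
    alternation between the scale bounds), with s the scale range and m the
    window length.  A degenerate scale (s = 0) gives F = 0 by convention.
    """
    window = np.asarray(window, dtype=float)
    s = scale_max - scale_min
    if s <= 0:
        logger.debug("degenerate scale range; F = 0 by convention")
        return 0.0
    if window.min() < scale_min or window.max() > scale_max:
        warnings.warn("window values outside scale bounds; clipping", stacklevel=2)
        window = np.clip(window, scale_min, scale_max)
    m = window.size
    total = sum(a / d for a, d in _run_decomposition(window))
    return float(total / (s * (m - 1)))


def distribution_measure(
    window: np.ndarray, scale_min: float, scale_max: float
) -> float:
    """Distribution measure D in [0, 1] of one backward window.

    The sorted window is compared against perfectly uniform coverage of the
    scale range: for every index pair (i, i + c) the empirical spread
    ``y[i+c] - y[i]`` is matched against the uniform spread ``c * s/(m-1)``,
    and only shortfalls (uniform minus empirical, floored at zero) count.
    D = 1 - total shortfall / total uniform spread, so a constant window
    scores 0 and an exactly uniformly-spaced window scores 1.
    """
    window = np.asarray(window, dtype=float)
    s = scale_max - scale_min
    if s <= 0:
        logger.debug("degenerate scale range; D = 0 by convention")
        return 0.0
    if window.min() < scale_min or window.max() > scale_max:
        warnings.warn("window values outside scale bounds; clipping", stacklevel=2)
        window = np.clip(window, scale_min, scale_max)
    y = np.sort(window)
    m = y.size
    u = s / (m - 1)
    i, j = np.triu_indices(m, k=1)
    uniform = (j - i) * u
    shortfall = np.maximum(uniform - (y[j] - y[i]), 0.0)
    return float(1.0 - shortfall.sum() / uniform.sum())


def complexity_trace(
    series: StepSeries, params: ComplexityParams = ComplexityParams()
) -> ComplexityTrace:
    """Per-day dynamic complexity over one imputed series.

    For each day n from ``window_days`` on, F and D are computed on the
    ``window_days`` values ending at day n and C = F * D.  Scale bounds are
    fixed per participant (observed min/max of the imputed series unless
    overridden), anchoring D to the participant's own attainable range.
    """
    y = series.steps
    if np.isnan(y).any():
        raise ValueError("complexity requires a complete (imputed) series")
    m = params.window_days
    if y.size < m:
        raise ValueError(f"series of {y.size} days is shorter than the {m}-day window")
    lo = params.scale_min if params.scale_min is not None else float(y.min())
    hi = params.scale_max if params.scale_max is not None else float(y.max())

    n = y.size
    F = np.full(n, np.nan)
    D = np.full(n, np.nan)
    for day in range(m, n + 1):  # 1-based day index
        w = y[day - m : day]
        F[day - 1] = fluctuation_intensity(w, lo, hi)
        D[day - 1] = distribution_measure(w, lo, hi)
    return ComplexityTrace(
        participant_id=series.participant_id, F=F, D=D, C=F * D, defined_from=m
    )


def local_dynamic_complexity(
    trace: ComplexityTrace, day: int, params: ComplexityParams = ComplexityParams()
) -> float:
    """LDC for one (1-based) day: max C over the preceding ``ldc_lag_days``.

    Raises if any required preceding day has undefined C.
    """
    lag = params.ldc_lag_days
    if day - lag < trace.defined_from:
        raise ValueError(
            f"day {day}: needs C defined on days {day - lag}..{day - 1} "
            f"(first defined day is {trace.defined_from})"
        )
    if day > trace.n_days + 1:
        raise ValueError(f"day {day} beyond series end")
    return float(trace.C[day - 1 - lag : day - 1].max())
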