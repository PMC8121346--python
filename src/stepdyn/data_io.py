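"""Step-series containers, CSV I/O, validity/inclusion filters, and imputation.

The pipeline's atomic input is one participant's daily step-count series on a
dense calendar grid.  Days without an observation are explicit missing entries
(NaN), never silent gaps, so that window statistics and day-indexed covariates
stay aligned with calendar time.

Preparation order is: wear-time validity -> inclusion check -> Kalman
imputation.  Each step is idempotent on its own output.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("stepdyn")

#: minutes/day of valid wear required for a day to count as observed
DEFAULT_MIN_WEAR_MINUTES = 600
#: minimum series length (days) for a participant to enter the analysis set
DEFAULT_MIN_DAYS = 90
#: maximum tolerated fraction of missing days (strict inequality)
DEFAULT_MAX_MISSING_FRAC = 0.20


@dataclass
class StepSeries:
    """One participant's daily step counts on a dense calendar grid.

    Parameters
    ----------
    participant_id : str
        Opaque participant identifier.
    start_date : datetime.date
        Calendar date of day 1.  Day indices used throughout the package are
        1-based offsets from this date.
    steps : numpy.ndarray of float
        One value per consecutive calendar day; ``NaN`` marks a missing day.
    wear_minutes : numpy.ndarray of float, optional
        Device wear time per day in [0, 1440]; absent for synthetic data.
    imputed_mask : numpy.ndarray of bool
        True exactly on days whose value was filled in by imputation.
    """

    participant_id: str
    start_date: _dt.date
    steps: np.ndarray
    wear_minutes: np.ndarray | None = None
    imputed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        if self.steps.ndim != 1 or self.steps.size == 0:
            raise ValueError("steps must be a non-empty 1-D sequence")
        observed = self.steps[~np.isnan(self.steps)]
        if np.any(observed < 0):
            raise ValueError(f"negative step counts for {self.participant_id!r}")
        if self.wear_minutes is not None:
            self.wear_minutes = np.asarray(self.wear_minutes, dtype=float)
            if self.wear_minutes.shape != self.steps.shape:
                raise ValueError("wear_minutes length must match steps")
            wm = self.wear_minutes[~np.isnan(self.wear_minutes)]
            if np.any((wm < 0) | (wm > 1440)):
                raise ValueError("wear_minutes must lie in [0, 1440]")
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(self.steps.shape, dtype=bool)
        else:
            self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
            if self.imputed_mask.shape != self.steps.shape:
                raise ValueError("imputed_mask length must match steps")

    @property
    def n_days(self) -> int:
        return int(self.steps.size)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.steps)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.steps).sum())

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    @property
    def weekend_mask(self) -> np.ndarray:
        """True on Saturdays and Sundays."""
        return self.dates.dayofweek.values >= 5

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "date": self.dates.date,
                "steps": self.steps,
                "imputed": self.imputed_mask,
            }
        )
        if self.wear_minutes is not None:
            df["wear_minutes"] = self.wear_minutes
        return df

    def copy(self) -> "StepSeries":
        return replace(
            self,
            steps=self.steps.copy(),
            wear_minutes=None if self.wear_minutes is None else self.wear_minutes.copy(),
            imputed_mask=self.imputed_mask.copy(),
        )


@dataclass(frozen=True)
class InclusionReport:
    """Outcome of the inclusion check for one participant."""

    participant_id: str
    n_days: int
    n_missing: int
    missing_frac: float
    included: bool
    reasons: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# CSV I/O — long format: participant_id, date (ISO-8601), steps[, wear_minutes]
# ---------------------------------------------------------------------------

def read_step_series(path) -> list[StepSeries]:
    """Read long-format daily records into dense per-participant series.

    Rows may be unsorted; calendar days absent from the file become missing
    entries so each returned series covers a gap-free date range.  Duplicate
    (participant, date) pairs and negative step counts are errors.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "date", "steps"}
    if not required.issubset(df.columns):
        raise ValueError(f"input must have columns {sorted(required)}; got {list(df.columns)}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"dates must be ISO-8601: {exc}") from exc

    dup = df.duplicated(subset=["participant_id", "date"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (participant, date) entry: {row['participant_id']!r} "
            f"on {row['date'].date()}"
        )
    if (df["steps"].dropna() < 0).any():
        bad = df[df["steps"] < 0].iloc[0]
        raise ValueError(f"negative steps for {bad['participant_id']!r} on {bad['date'].date()}")

    has_wear = "wear_minutes" in df.columns
    out: list[StepSeries] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.set_index("date").sort_index()
        grid = pd.date_range(grp.index.min(), grp.index.max(), freq="D")
        grp = grp.reindex(grid)
        out.append(
            StepSeries(
                participant_id=str(pid),
                start_date=grid[0].date(),
                steps=grp["steps"].to_numpy(dtype=float),
                wear_minutes=grp["wear_minutes"].to_numpy(dtype=float) if has_wear else None,
                imputed_mask=grp["imputed"].fillna(False).to_numpy(dtype=bool)
                if "imputed" in grp.columns
                else None,
            )
        )
    return out


def write_step_series(series_list: list[StepSeries], path) -> None:
    """Write series to the long-format CSV dialect (missing steps as empty)."""
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_wear_validity(
    series: StepSeries, min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES
) -> StepSeries:
    """Mark days with insufficient device wear as missing.

    Days whose wear time falls below ``min_wear_minutes`` are treated as not
    observed.  Series without a wear channel (synthetic cohorts) pass through
    unchanged with a warning.
    """
    if series.wear_minutes is None:
        warnings.warn(
            f"{series.participant_id}: no wear_minutes channel; validity filter skipped",
            stacklevel=2,
        )
        return series
    out = series.copy()
    invalid = (~np.isnan(out.wear_minutes)) & (out.wear_minutes < min_wear_minutes)
    n_affected = int((invalid & ~np.isnan(out.steps)).sum())
    out.steps[invalid] = np.nan
    if n_affected:
        logger.info(
            "%s: %d day(s) below %d wear minutes set to missing",
            series.participant_id, n_affected, min_wear_minutes,
        )
    return out


def check_inclusion(
    series: StepSeries,
    min_days: int = DEFAULT_MIN_DAYS,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
) -> InclusionReport:
    """Apply the analysis-set inclusion rule.

    A participant is included iff the series spans at least ``min_days``
    calendar days and strictly less than ``max_missing_frac`` of them are
    missing.
    """
    if series.n_days == 0:
        raise ValueError("empty series")
    n, n_miss = series.n_days, series.n_missing
    frac = n_miss / n
    reasons = []
    if n < min_days:
        reasons.append(f"min_days: {n} < {min_days}")
    if not frac < max_missing_frac:
        reasons.append(f"missing_frac: {frac:.3f} >= {max_missing_frac}")
    return InclusionReport(
        participant_id=series.participant_id,
        n_days=n,
        n_missing=n_miss,
        missing_frac=frac,
        included=not reasons,
        reasons=tuple(reasons),
    )


def write_inclusion_reports(reports: list[InclusionReport], path) -> None:
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in reports],
            "n_days": [r.n_days for r in reports],
            "n_missing": [r.n_missing for r in reports],
            "missing_frac": [r.missing_frac for r in reports],
            "included": [r.included for r in reports],
            "reasons": ["; ".join(r.reasons) for r in reports],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_kalman(series: StepSeries) -> StepSeries:
    """Fill missing days with Kalman-smoothed state estimates.

    A local-level structural model (random walk + observation noise) is fitted
    by maximum likelihood on the observed days; missing days are replaced by
    the smoothed level, clipped at zero.  Observed values are never altered.
    If the likelihood optimisation fails, missing days are linearly
    interpolated instead (with edge extension) and a warning is logged.
    """
    miss = series.missing_mask
    if not miss.any():
        return series
    n_obs = int((~miss).sum())
    if n_obs == 0:
        raise ValueError(f"{series.participant_id}: all days missing, cannot impute")
    if n_obs < 2:
        raise ValueError(f"{series.participant_id}: need >= 2 observed days to impute")

    out = series.copy()
    filled = _kalman_fill(out.steps)
    if filled is None:
        warnings.warn(
            f"{series.participant_id}: state-space fit failed; "
            "falling back to linear interpolation",
            stacklevel=2,
        )
        filled = (
            pd.Series(out.steps)
            .interpolate(method="linear", limit_direction="both")
            .to_numpy()
        )
    out.steps[miss] = np.clip(filled[miss], 0.0, None)
    out.imputed_mask = series.imputed_mask | miss
    return out


def _kalman_fill(y: np.ndarray) -> np.ndarray | None:
    """Smoothed level from a local-level model; None on optimisation failure."""
    from statsmodels.tsa.statespace.structural import UnobservedComponents

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = UnobservedComponents(y, level="local level")
            res = model.fit(disp=False, maxiter=200)
        except Exception:  # noqa: BLE001 - optimizer/LAPACK failures trigger fallback
            return None
    if not np.all(np.isfinite(res.params)):
        return None
    level = np.asarray(res.smoothed_state[0])
    if not np.all(np.isfinite(level)):
        return None
    return level


def prepare_series(
    series: StepSeries,
    min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES,
    min_days: int = DEFAULT_MIN_DAYS,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
) -> tuple[StepSeries | None, InclusionReport]:
    """Validity filter -> inclusion check -> imputation, in that order.

    Returns ``(imputed series, report)`` for included participants and
    ``(None, report)`` for excluded ones.
    """
    if series.wear_minutes is not None:
        series = apply_wear_validity(series, min_wear_minutes)
    report = check_inclusion(series, min_days, max_missing_frac)
    if not report.included:
        return None, report
    return impute_kalman(series), report
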