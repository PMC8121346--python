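"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stepdyn import CohortConfig, generate_cohort


def simulate_hazard_records(
    n_participants: int,
    n_days: int,
    seed: int,
    intercept: float = -4.0,
    beta_time: float = -0.15,
    beta_duration_raw: float = 0.01,
    beta_ldc: float = 0.0,
    re_intercept_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate day-level event-history records from a known hazard model.

    ``time`` enters z-scored over the participant-day grid, ``duration`` on
    the raw day scale (coefficient per day), and ``ldc`` as i.i.d. standard
    normal so its fitted standardized coefficient is directly comparable to
    ``beta_ldc``.  Events feed back into the duration clock, reproducing the
    at-risk dynamics of the real table.
    """
    rng = np.random.default_rng(seed)
    days = np.arange(1, n_days + 1)
    time_z = (days - days.mean()) / days.std(ddof=1)
    frames = []
    for i in range(n_participants):
        b0 = intercept + re_intercept_sd * rng.standard_normal()
        ldc = rng.standard_normal(n_days)
        duration = np.zeros(n_days, dtype=int)
        outcome = np.zeros(n_days, dtype=int)
        since = 0
        for t in range(n_days):
            since += 1
            duration[t] = since
            eta = b0 + beta_time * time_z[t] + beta_duration_raw * since + beta_ldc * ldc[t]
            if rng.random() < 1.0 / (1.0 + np.exp(-eta)):
                outcome[t] = 1
                since = 0
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": f"S{i:03d}",
                    "day": days,
                    "outcome": outcome,
                    "is_gain": outcome,  # direction split unused in these checks
                    "is_loss": outcome,
                    "time": days,
                    "duration": duration,
                    "ldc": ldc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten complete (no missing days) synthetic series with ground truth."""
    config = CohortConfig(
        n_participants=10,
        missing_frac_dist=(0.0, 0.0),
        precursor_sd_multiplier_loss=1.0,
        seed=11,
    )
    return generate_cohort(config)
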