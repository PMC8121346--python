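"""Event-history table construction and the mixed-effects hazard model."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from _oracles import recount_durations
from conftest import simulate_hazard_records
from stepdyn import (
    ComplexityParams,
    ModelSpec,
    StepSeries,
    build_event_table,
    complexity_trace,
    compute_odds_ratios,
    fit_event_model,
    standardize_predictors,
)
from stepdyn.detection import TransitionEvent
from stepdyn.mixed_logit import MixedLogitModel


def _trace(pid, n_days, seed=0):
    import datetime

    rng = np.random.default_rng(seed)
    s = StepSeries(pid, datetime.date(2019, 6, 1), rng.uniform(3000, 12000, n_days))
    return complexity_trace(s)


def _event(pid, day, direction="gain"):
    sign = 1 if direction == "gain" else -1
    return TransitionEvent(pid, day, direction, sign * 3000.0, sign * 0.4, 7000.0,
                           7000.0 + sign * 3000.0)


class TestBuildEventTable:
    def test_censored_participant_contributes_all_zero_outcomes(self):
        table = build_event_table([], {"A": _trace("A", 109)})
        # warm-up = window (7) + lag (3) days; days 10..109 usable
        assert len(table) == 100
        assert (table["outcome"] == 0).all()
        assert table["duration"].is_monotonic_increasing

    def test_duration_resets_the_day_after_each_event(self):
        events = [_event("A", 30, "gain"), _event("A", 60, "loss")]
        table = build_event_table(events, {"A": _trace("A", 100)}).set_index("day")
        assert table.loc[45, "duration"] == 15
        assert table.loc[61, "duration"] == 1
        assert table.loc[30, "duration"] == 30
        assert table.loc[60, "duration"] == 30

    def test_durations_match_single_pass_recount(self):
        events = [_event("A", d) for d in (25, 40, 90)]
        table = build_event_table(events, {"A": _trace("A", 120)})
        oracle = recount_durations([25, 40, 90], 120)
        for _, row in table.iterrows():
            assert row["duration"] == oracle[int(row["day"]) - 1]

    def test_outcome_sum_equals_events_with_defined_ldc(self, small_cohort):
        from stepdyn import detect

        traces, events = {}, []
        for series, _ in small_cohort:
            _, evs = detect(series)
            events.extend(evs)
            traces[series.participant_id] = complexity_trace(series)
        params = ComplexityParams()
        table = build_event_table(events, traces, params)
        first_usable = params.window_days + params.ldc_lag_days
        n_expected = sum(1 for e in events if e.day >= first_usable)
        assert int(table["outcome"].sum()) == n_expected
        assert int(table["is_gain"].sum() + table["is_loss"].sum()) == n_expected

    def test_event_day_outside_series_raises(self):
        with pytest.raises(ValueError, match="outside"):
            build_event_table([_event("A", 500)], {"A": _trace("A", 100)})


class TestStandardize:
    def test_zscore_and_roundtrip(self):
        df = simulate_hazard_records(5, 80, seed=0)
        out, scaling = standardize_predictors(df)
        for col in ("time", "duration", "ldc"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
            mean, sd = scaling[col]
            np.testing.assert_allclose(out[col] * sd + mean, df[col], rtol=1e-12)

    def test_zero_variance_predictor_raises_by_name(self):
        df = simulate_hazard_records(5, 80, seed=1)
        df["ldc"] = 0.5
        with pytest.raises(ValueError, match="ldc"):
            standardize_predictors(df)

    def test_or_per_sd_equals_scaled_raw_coefficient(self):
        """exp(beta_std) from the z-scored fit == exp(beta_raw * SD) from the raw fit."""
        df = simulate_hazard_records(30, 120, seed=2, beta_ldc=0.4, re_intercept_sd=0.4)
        df["y"] = df["outcome"].astype(float)
        sds = {c: df[c].std(ddof=1) for c in ("time", "duration", "ldc")}
        std, _ = standardize_predictors(df)

        def fit(frame):
            X = np.column_stack(
                [np.ones(len(frame)), frame.time, frame.duration, frame.ldc]
            )
            m = MixedLogitModel(X, frame.y.to_numpy(), frame.participant_id.to_numpy(),
                                re_cols=[0], fe_names=["intercept", "time", "duration", "ldc"])
            return m.fit()

        raw, zed = fit(df), fit(std)
        for j, name in [(1, "time"), (2, "duration"), (3, "ldc")]:
            assert np.exp(zed.beta[j]) == pytest.approx(
                np.exp(raw.beta[j] * sds[name]), rel=0.01
            )


class TestFitEventModel:
    def test_zero_heterogeneity_matches_plain_logistic(self):
        import statsmodels.api as sm

        df = simulate_hazard_records(40, 120, seed=3, beta_ldc=0.3)
        fit = fit_event_model(df, ModelSpec(outcome_filter="both", ci_method="wald"))
        std, _ = standardize_predictors(df)
        X = sm.add_constant(std[["time", "duration", "ldc"]].to_numpy())
        glm = sm.Logit(std["outcome"].to_numpy(), X).fit(disp=False)
        mixed = [fit.coefficients[k] for k in ("intercept", "time", "duration", "ldc")]
        np.testing.assert_allclose(mixed, glm.params, atol=0.02)

    def test_outcome_filters_subset_participants(self):
        df = simulate_hazard_records(20, 150, seed=4)
        rng = np.random.default_rng(0)
        # split each participant's events into gains/losses at random
        is_gain = (rng.random(len(df)) < 0.5) & (df["outcome"] == 1)
        df["is_gain"] = is_gain.astype(int)
        df["is_loss"] = df["outcome"] - df["is_gain"]
        both = fit_event_model(df, ModelSpec("both", ci_method="wald"))
        gains = fit_event_model(df, ModelSpec("gains_only", ci_method="wald"))
        losses = fit_event_model(df, ModelSpec("losses_only", ci_method="wald"))
        assert both.n_participants >= gains.n_participants
        assert both.n_participants >= losses.n_participants
        assert gains.n_events + losses.n_events == both.n_events
        had_gain = df.groupby("participant_id")["is_gain"].max()
        assert gains.n_participants == int((had_gain > 0).sum())

    def test_single_class_outcome_raises(self):
        df = simulate_hazard_records(5, 50, seed=5)
        df[["outcome", "is_gain", "is_loss"]] = 0
        with pytest.raises(ValueError, match="single class"):
            fit_event_model(df, ModelSpec("both"))

    def test_profile_and_wald_cis_agree_when_likelihood_is_quadratic(self):
        df = simulate_hazard_records(50, 200, seed=6, beta_ldc=0.3, re_intercept_sd=0.3)
        fit = fit_event_model(df, ModelSpec("both", ci_method="profile"))
        X = None  # profile bounds already computed inside fit
        wald_fit = fit_event_model(df, ModelSpec("both", ci_method="wald"))
        for name in ("time", "duration", "ldc"):
            for col in ("ci_low", "ci_high"):
                prof = fit.odds_ratios.loc[name, col]
                wald = wald_fit.odds_ratios.loc[name, col]
                assert prof == pytest.approx(wald, rel=0.05)
        assert fit.odds_ratios.loc["ldc", "OR"] == pytest.approx(
            np.exp(fit.coefficients["ldc"])
        )


class TestAgainstLme4:
    def test_fixed_effects_and_re_sd_match_glmer(self, tmp_path):
        """Cross-check the Laplace fitter against lme4 on one seeded dataset."""
        df = simulate_hazard_records(
            40, 120, seed=7, beta_ldc=0.4, re_intercept_sd=0.5
        )
        std, _ = standardize_predictors(df)
        std["y"] = std["outcome"]
        csv = tmp_path / "records.csv"
        std.to_csv(csv, index=False)

        X = np.column_stack([np.ones(len(std)), std.time, std.duration, std.ldc])
        m = MixedLogitModel(X, std.y.to_numpy().astype(float),
                            std.participant_id.to_numpy(),
                            re_cols=[0, 3], fe_names=["intercept", "time", "duration", "ldc"])
        fit = m.fit()

        rscript = tmp_path / "fit.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            f <- glmer(y ~ time + duration + ldc + (1 + ldc || participant_id),
                       data = d, family = binomial)
            vc <- as.data.frame(VarCorr(f))
            cat(fixef(f), vc$sdcor, -2 * as.numeric(logLik(f)), sep = ',')
        """))
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().split(",")]
        r_beta, r_sd, r_m2ll = vals[:4], vals[4:6], vals[6]
        np.testing.assert_allclose(fit.beta, r_beta, atol=0.06)
        np.testing.assert_allclose(np.sort(fit.re_sd), np.sort(r_sd), atol=0.05)
        assert fit.deviance == pytest.approx(r_m2ll, abs=2.0)


def test_or_table_shape_and_exp_relation():
    df = simulate_hazard_records(15, 100, seed=8, beta_ldc=0.2)
    fit = fit_event_model(df, ModelSpec("both", ci_method="wald"))
    ors = fit.odds_ratios
    assert list(ors.index) == ["intercept", "time", "duration", "ldc"]
    assert (ors["ci_low"] <= ors["OR"]).all() and (ors["OR"] <= ors["ci_high"]).all()
    for name, coef in fit.coefficients.items():
        assert ors.loc[name, "OR"] == pytest.approx(np.exp(coef))
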