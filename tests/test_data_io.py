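"""CSV round-tripping, validity/inclusion filters, and Kalman imputation."""

import datetime

import numpy as np
import pytest

from _oracles import ar1_kalman_impute
from stepdyn import (
    StepSeries,
    apply_wear_validity,
    check_inclusion,
    impute_kalman,
    prepare_series,
    read_step_series,
    write_step_series,
)

D0 = datetime.date(2019, 6, 1)


class TestReadWrite:
    def test_absent_days_become_missing_on_a_dense_grid(self, tmp_path):
        p = tmp_path / "in.csv"
        p.write_text(
            "participant_id,date,steps\n"
            "A,2019-06-01,5000\n"
            "A,2019-06-03,7000\n"
            "B,2019-06-01,4000\n"
        )
        series = read_step_series(p)
        a = next(s for s in series if s.participant_id == "A")
        assert a.n_days == 3
        assert np.isnan(a.steps[1])
        assert a.steps[0] == 5000 and a.steps[2] == 7000

    def test_write_then_read_is_identity_on_the_dense_grid(self, tmp_path):
        steps = np.array([5000.0, np.nan, 7000.0, 8000.0])
        s = StepSeries("A", D0, steps, wear_minutes=np.array([900.0, 0, 800, 1200]))
        path = tmp_path / "out.csv"
        write_step_series([s], path)
        (back,) = read_step_series(path)
        assert back.participant_id == "A"
        assert back.start_date == D0
        np.testing.assert_array_equal(back.steps, steps)
        np.testing.assert_array_equal(back.wear_minutes, s.wear_minutes)

    def test_duplicate_participant_date_raises(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "participant_id,date,steps\nA,2019-06-01,5000\nA,2019-06-01,6000\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_step_series(p)

    def test_negative_steps_and_bad_dates_raise(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("participant_id,date,steps\nA,2019-06-01,-5\n")
        with pytest.raises(ValueError, match="negative"):
            read_step_series(p)
        p.write_text("participant_id,date,steps\nA,June 1st,5\n")
        with pytest.raises(ValueError, match="ISO"):
            read_step_series(p)

    def test_unsorted_rows_are_reordered(self, tmp_path):
        p = tmp_path / "shuffled.csv"
        p.write_text(
            "participant_id,date,steps\n"
            "A,2019-06-03,7000\nA,2019-06-01,5000\nA,2019-06-02,6000\n"
        )
        (s,) = read_step_series(p)
        np.testing.assert_array_equal(s.steps, [5000, 6000, 7000])


class TestWearValidity:
    def test_low_wear_days_become_missing(self):
        s = StepSeries("A", D0, np.array([5000.0, 6000, 7000]),
                       wear_minutes=np.array([1440.0, 300, 700]))
        out = apply_wear_validity(s, 600)
        assert np.isnan(out.steps[1])
        assert out.steps[0] == 5000 and out.steps[2] == 7000

    def test_all_valid_days_unchanged(self):
        s = StepSeries("A", D0, np.array([5000.0, 6000]),
                       wear_minutes=np.array([600.0, 1440]))
        np.testing.assert_array_equal(apply_wear_validity(s, 600).steps, s.steps)

    def test_zero_min_wear_is_a_no_op(self):
        s = StepSeries("A", D0, np.array([5000.0, 6000]),
                       wear_minutes=np.array([0.0, 10]))
        np.testing.assert_array_equal(apply_wear_validity(s, 0).steps, s.steps)

    def test_missing_wear_channel_warns_and_passes_through(self):
        s = StepSeries("A", D0, np.array([5000.0, 6000]))
        with pytest.warns(UserWarning, match="wear_minutes"):
            out = apply_wear_validity(s)
        np.testing.assert_array_equal(out.steps, s.steps)


class TestInclusion:
    def _series(self, n_days, n_missing):
        steps = np.full(n_days, 5000.0)
        steps[:n_missing] = np.nan
        return StepSeries("A", D0, steps)

    @pytest.mark.parametrize(
        "n_days,n_missing,included,reason",
        [
            (100, 19, True, None),  # 0.19 < 0.20: in
            (100, 20, False, "missing_frac"),  # 0.20 is not < 0.20: out
            (89, 0, False, "min_days"),
            (90, 0, True, None),
        ],
    )
    def test_boundary_arithmetic(self, n_days, n_missing, included, reason):
        rep = check_inclusion(self._series(n_days, n_missing))
        assert rep.included is included
        assert rep.missing_frac == pytest.approx(n_missing / n_days)
        if reason:
            assert any(reason in r for r in rep.reasons)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            StepSeries("A", D0, np.array([]))


class TestKalmanImputation:
    def test_complete_series_is_identity(self):
        s = StepSeries("A", D0, np.full(30, 8000.0))
        out = impute_kalman(s)
        np.testing.assert_array_equal(out.steps, s.steps)
        assert not out.imputed_mask.any()

    def test_constant_series_imputes_the_constant(self):
        steps = np.full(60, 8000.0)
        steps[[20, 21, 40]] = np.nan
        out = impute_kalman(StepSeries("A", D0, steps))
        assert not np.isnan(out.steps).any()
        np.testing.assert_allclose(out.steps[[20, 21, 40]], 8000.0, rtol=1e-3)
        assert set(np.flatnonzero(out.imputed_mask)) == {20, 21, 40}

    def test_observed_values_never_altered(self):
        rng = np.random.default_rng(0)
        steps = rng.uniform(3000, 12000, 120)
        masked = steps.copy()
        idx = rng.choice(120, 15, replace=False)
        masked[idx] = np.nan
        out = impute_kalman(StepSeries("A", D0, masked))
        obs = np.setdiff1d(np.arange(120), idx)
        np.testing.assert_array_equal(out.steps[obs], steps[obs])
        assert not np.isnan(out.steps).any()
        assert np.all(out.steps >= 0)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(1)
        steps = rng.uniform(3000, 9000, 100)
        steps[rng.choice(100, 10, replace=False)] = np.nan
        once = impute_kalman(StepSeries("A", D0, steps))
        twice = impute_kalman(once)
        np.testing.assert_array_equal(once.steps, twice.steps)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            impute_kalman(StepSeries("A", D0, np.full(10, np.nan)))

    def test_rmse_close_to_exact_smoother_on_ar1_series(self):
        """Fitted state-space imputation vs the exact smoother at true parameters."""
        phi, innov_sd, level = 0.6, 800.0, 9000.0
        rmse_pkg, rmse_oracle = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 250
            x = np.zeros(n)
            x[0] = rng.normal(0, innov_sd / np.sqrt(1 - phi**2))
            for t in range(1, n):
                x[t] = phi * x[t - 1] + rng.normal(0, innov_sd)
            y = level + x
            idx = rng.choice(np.arange(1, n - 1), n // 10, replace=False)
            masked = y.copy()
            masked[idx] = np.nan
            out = impute_kalman(StepSeries("A", D0, masked))
            oracle = level + ar1_kalman_impute(masked - level, phi, innov_sd)
            rmse_pkg.append(np.sqrt(np.mean((out.steps[idx] - y[idx]) ** 2)))
            rmse_oracle.append(np.sqrt(np.mean((oracle[idx] - y[idx]) ** 2)))
        assert np.mean(rmse_pkg) <= 1.10 * np.mean(rmse_oracle)

    def test_kalman_beats_participant_mean_on_ar_series(self):
        phi, innov_sd, level = 0.7, 700.0, 8000.0
        kalman_err, mean_err = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 200
            x = np.zeros(n)
            for t in range(1, n):
                x[t] = phi * x[t - 1] + rng.normal(0, innov_sd)
            y = level + x
            idx = rng.choice(np.arange(1, n - 1), 20, replace=False)
            masked = y.copy()
            masked[idx] = np.nan
            out = impute_kalman(StepSeries("A", D0, masked))
            kalman_err.append(np.mean((out.steps[idx] - y[idx]) ** 2))
            mean_err.append(np.mean((np.nanmean(masked) - y[idx]) ** 2))
        assert np.mean(kalman_err) < np.mean(mean_err)


class TestPrepare:
    def test_pipeline_order_and_exclusion(self):
        wear = np.full(100, 1000.0)
        wear[:25] = 100.0  # invalidated by wear rule -> 25% missing -> excluded
        s = StepSeries("A", D0, np.full(100, 6000.0), wear_minutes=wear)
        cooked, report = prepare_series(s)
        assert cooked is None
        assert not report.included
        assert report.n_missing == 25

    def test_included_participant_comes_back_complete(self):
        steps = np.full(120, 6000.0)
        steps[10:15] = np.nan
        cooked, report = prepare_series(StepSeries("A", D0, steps))
        assert report.included
        assert not np.isnan(cooked.steps).any()
        assert cooked.imputed_mask.sum() == 5
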