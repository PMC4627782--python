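"""Trend, periodicity, covariate, and ARMA estimators on known ground truth."""

import numpy as np
import pytest

from rsnlong import (
    EstimationError,
    GroundTruth,
    InvalidArgumentError,
    fisher_g_test,
    fit_arma,
    fit_linear_trend,
    make_calendar,
    permutation_null,
    robust_spectrum,
    simulate_outcome_series,
)
from rsnlong.core import OutcomeSeries, SessionCalendar
from rsnlong.timeseries import (
    ANNUAL_FREQUENCY,
    _batch_slope_t,
    fisher_g_pvalue,
    fourier_grid,
    trend_statistic,
)


def series_from(calendar, values, **kw):
    return OutcomeSeries(calendar=calendar, values=np.asarray(values, float), **kw)


class TestLinearTrend:
    def test_noiseless_line_recovered_exactly(self, study_calendar):
        s = simulate_outcome_series(
            study_calendar, GroundTruth(intercept=0.77, slope=1.94e-4)
        )
        r = fit_linear_trend(s)
        assert r.intercept == pytest.approx(0.77, abs=1e-12)
        assert r.slope == pytest.approx(1.94e-4, abs=1e-15)

    def test_constant_series_has_zero_slope_and_f(self, study_calendar):
        s = simulate_outcome_series(study_calendar, GroundTruth(intercept=1.0))
        r = fit_linear_trend(s)
        assert r.slope == 0.0 and r.F == 0.0

    def test_slope_regressor_is_calendar_week_not_session_ordinal(self):
        cal = SessionCalendar(total_weeks=10, observed_weeks=np.array([0, 1, 9]))
        s = series_from(cal, [0.0, 1.0, 9.0])  # y = t exactly
        assert fit_linear_trend(s).slope == pytest.approx(1.0, abs=1e-12)

    def test_too_short_rejected(self):
        cal = SessionCalendar(total_weeks=5, observed_weeks=np.array([0, 4]))
        with pytest.raises(InvalidArgumentError):
            fit_linear_trend(series_from(cal, [1.0, 2.0]))

    def test_slope_unbiased_under_noise(self, study_calendar):
        # mean bias < 1 SE(mean) over 500 noisy replicates of a known line
        slopes = []
        for i in range(500):
            s = simulate_outcome_series(
                study_calendar,
                GroundTruth(intercept=0.77, slope=1.94e-4, noise_sd=0.02, seed=i),
            )
            slopes.append(fit_linear_trend(s).slope)
        bias = np.mean(slopes) - 1.94e-4
        assert abs(bias) < np.std(slopes) / np.sqrt(500)


class TestPermutation:
    def test_add_one_estimator_minimum(self, study_calendar):
        s = simulate_outcome_series(
            study_calendar, GroundTruth(slope=0.1, noise_sd=0.01, seed=0)
        )
        p = permutation_null(s, trend_statistic, n_iter=1000, seed=1)
        assert p == pytest.approx(1 / 1001, abs=1e-12)

    def test_zero_iterations_rejected(self, white_noise_series):
        with pytest.raises(InvalidArgumentError):
            permutation_null(white_noise_series(0), trend_statistic, n_iter=0)

    def test_batch_statistic_agrees_with_scalar(self, white_noise_series):
        s = white_noise_series(3)
        p1 = permutation_null(s, trend_statistic, n_iter=200, seed=4)
        p2 = permutation_null(
            s, trend_statistic, n_iter=200, seed=4, batch_statistic_fn=_batch_slope_t
        )
        assert p1 == p2


class TestRobustSpectrum:
    def test_annual_sinusoid_peaks_at_annual_bin(self, study_calendar):
        s = simulate_outcome_series(
            study_calendar, GroundTruth(annual_amplitude=1.0, noise_sd=0.0)
        )
        sp = robust_spectrum(s)
        grid = fourier_grid(185)
        nearest = grid[np.argmin(np.abs(grid - ANNUAL_FREQUENCY))]
        assert sp.argmax_frequency() == pytest.approx(nearest)

    def test_constant_series_flags_flat_spectrum(self, study_calendar):
        s = simulate_outcome_series(study_calendar, GroundTruth(intercept=3.0))
        assert robust_spectrum(s).flat

    def test_matches_periodogram_without_missing_weeks(self, rng):
        # complete sampling: regression spectrum == classical periodogram
        cal = make_calendar(64, 64, seed=0)
        for _ in range(50):
            y = rng.normal(size=64)
            sp = robust_spectrum(series_from(cal, y))
            fft = np.fft.rfft(y - y.mean())
            pgram = np.abs(fft[1 : len(sp.power) + 1]) ** 2 / 64
            ratio = sp.power / pgram
            np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_white_noise_has_no_persistent_peak(self, study_calendar):
        # no frequency exceeds 3x median power persistently across seeds
        top_bins = []
        for i in range(20):
            s = simulate_outcome_series(study_calendar, GroundTruth(noise_sd=1.0, seed=i))
            sp = robust_spectrum(s)
            exceed = np.nonzero(sp.power > 3 * np.median(sp.power))[0]
            top_bins.extend(exceed.tolist())
        # some bins exceed by chance, but none in most seeds
        if top_bins:
            _, counts = np.unique(top_bins, return_counts=True)
            assert counts.max() <= 10


class TestFisherG:
    def test_all_power_at_on_grid_target_gives_g_one(self):
        # sinusoid exactly on a Fourier bin of a complete calendar: no leakage
        cal = make_calendar(185, 185, seed=0)
        s = simulate_outcome_series(
            cal, GroundTruth(annual_amplitude=1.0, annual_period=185 / 4)
        )
        r = fisher_g_test(robust_spectrum(s), target_frequency=4 / 185)
        assert r.peak_at_target
        assert r.g_statistic > 0.999
        assert r.p < 1e-10

    def test_off_grid_annual_sinusoid_still_detected(self, study_calendar):
        # the annual frequency sits between grid bins; power leaks but the
        # peak stays on the nearest bin and the test fires
        s = simulate_outcome_series(
            study_calendar, GroundTruth(annual_amplitude=1.0, noise_sd=0.0)
        )
        r = fisher_g_test(robust_spectrum(s))
        assert r.peak_at_target
        assert r.g_statistic > 0.3
        assert r.p < 1e-10

    def test_flat_spectrum_share_is_one_over_m(self):
        from rsnlong.timeseries import SpectrumResult

        m = 20
        sp = SpectrumResult(frequencies=np.linspace(0.01, 0.5, m), power=np.ones(m))
        r = fisher_g_test(sp, target_frequency=0.25)
        assert r.g_statistic == pytest.approx(1 / m)

    def test_pvalue_formula_matches_simulation(self, rng):
        # exact null distribution vs direct Monte Carlo of the max share
        m = 12
        reps = 4000
        gmax = np.empty(reps)
        for i in range(reps):
            e = rng.exponential(size=m)
            gmax[i] = e.max() / e.sum()
        for g0 in (0.2, 0.3, 0.4):
            emp = np.mean(gmax > g0)
            assert fisher_g_pvalue(g0, m) == pytest.approx(
                emp, abs=4 * np.sqrt(emp * (1 - emp) / reps) + 0.005
            )

    def test_off_grid_target_snapped_and_recorded(self, study_calendar):
        s = simulate_outcome_series(
            study_calendar, GroundTruth(annual_amplitude=1.0, noise_sd=0.0)
        )
        r = fisher_g_test(robust_spectrum(s), target_frequency=0.0192)
        assert r.target_frequency == 0.0192
        assert r.snapped_frequency in fourier_grid(185)


class TestCovariate:
    def test_self_correlation_is_one(self, study_calendar):
        import pandas as pd

        from rsnlong.synthetic import DEFAULT_START_DATE, week_dates
        from rsnlong.timeseries import correlate_covariate

        s = simulate_outcome_series(study_calendar, GroundTruth(noise_sd=1.0, seed=2))
        dates = pd.to_datetime(week_dates(study_calendar, DEFAULT_START_DATE))
        cov = pd.Series(s.values, index=dates)
        r = correlate_covariate(s, cov, n_perm=99, seed=0)
        assert r.r == pytest.approx(1.0)
        r2 = correlate_covariate(s, -cov, n_perm=99, seed=0)
        assert r2.r == pytest.approx(-1.0)

    def test_noisy_phase_aligned_annual_pair(self, study_calendar):
        from rsnlong import simulate_covariate
        from rsnlong.timeseries import correlate_covariate

        s = simulate_outcome_series(
            study_calendar,
            GroundTruth(annual_amplitude=1.0, noise_sd=0.2, seed=6),
        )
        cov = simulate_covariate(
            study_calendar, annual_amplitude=1.0, noise_sd=0.2, seed=7
        )
        r = correlate_covariate(s, cov, n_perm=199, seed=0)
        assert r.r > 0.9
        assert r.p_perm < 0.05


class TestARMA:
    def test_ar1_coefficient_consistency_large_n(self):
        # S3-convention a1=-0.5, i.e. y_t = 0.5 y_{t-1} + e_t
        cal = make_calendar(1200, 1000, seed=3)
        s = simulate_outcome_series(
            cal, GroundTruth(ar_coeffs=(-0.5,), noise_sd=1.0, seed=4)
        )
        m = fit_arma(s, refine=False)
        assert m.ar_order == 1
        assert m.ar_coeffs[0] == pytest.approx(-0.5, abs=0.08)

    def test_short_series_rejected(self):
        cal = make_calendar(12, 10, seed=0)
        s = simulate_outcome_series(cal, GroundTruth(noise_sd=1.0, seed=1))
        with pytest.raises(EstimationError):
            fit_arma(s)

    def test_white_noise_selects_no_persistence(self, white_noise_series):
        m = fit_arma(white_noise_series(11))
        assert (m.ar_order, m.ma_order) == (0, 0)
        assert not m.has_persistence

    def test_candidate_table_contains_all_admissible_orders(self, white_noise_series):
        m = fit_arma(white_noise_series(12))
        assert (0, 0) in m.candidates
        assert (1, 1) in m.candidates

    def test_selected_model_is_stationary_and_invertible(self, study_calendar):
        s = simulate_outcome_series(
            study_calendar,
            GroundTruth(ar_coeffs=(-0.7,), ma_coeffs=(0.7,), noise_sd=1.0, seed=21),
        )
        m = fit_arma(s)
        for coeffs in (m.ar_coeffs, m.ma_coeffs):
            if coeffs.size:
                roots = np.roots(np.r_[1.0, coeffs][::-1])
                assert np.all(np.abs(roots) > 1.0)

    def test_loglik_matches_kalman_filter_oracle(self, study_calendar):
        # exact Gaussian likelihood on gappy samples == statsmodels Kalman ARIMA
        from statsmodels.tsa.arima.model import ARIMA

        from rsnlong.timeseries import _gaussian_loglik, deseasonalize

        s = simulate_outcome_series(
            study_calendar,
            GroundTruth(ar_coeffs=(-0.7,), ma_coeffs=(0.7,), noise_sd=1.0, seed=33),
        )
        x = deseasonalize(s)
        y = np.full(185, np.nan)
        y[s.weeks] = x
        sm = ARIMA(y, order=(1, 0, 1), trend="n").fit()
        ll_mine, _ = _gaussian_loglik(s.weeks, x, -sm.arparams, sm.maparams)
        assert ll_mine == pytest.approx(sm.llf, abs=1e-4)
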