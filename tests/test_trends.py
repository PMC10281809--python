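import datetime as dt

import numpy as np
import pytest

from reefspawn.synthetic import SpawningRegime, sample_hatch_dates
from reefspawn.trends import (
    bin_hatch_dates,
    detect_peaks,
    fit_spawning_smooth,
    split_austral_years,
    summarize_peaks,
)

K_GRID = (10, 16)  # compact basis grid keeps repeated fits quick
P_GRID = np.linspace(1.1, 1.9, 5)


def _year_series(components, n, seed, year=2020):
    regime = SpawningRegime(
        components=components,
        background_rate=0.0,
        date_range=(dt.date(year, 7, 1), dt.date(year + 1, 6, 30)),
    )
    dates = sample_hatch_dates(regime, n, seed=seed)
    return bin_hatch_dates(dates, year)


class TestBinning:
    def test_365_day_year_has_73_five_day_bins(self):
        s = bin_hatch_dates([], 2018)  # 2018-07-01 .. 2019-06-30
        assert len(s.counts) == 73
        assert np.all(s.bin_days == 5)
        assert s.counts.sum() == 0

    def test_leap_spanning_year_last_bin_absorbs_extra_day(self):
        s = bin_hatch_dates([], 2019)  # contains 2020-02-29
        assert np.all(s.bin_days[:-1] == 5) and s.bin_days[-1] == 6

    def test_one_date_per_day_fills_every_bin(self):
        days = [dt.date(2018, 7, 1) + dt.timedelta(days=i) for i in range(365)]
        s = bin_hatch_dates(days, 2018)
        assert np.all(s.counts == 5)

    def test_out_of_year_dates_ignored_and_counted(self):
        s = bin_hatch_dates([dt.date(2018, 6, 30), dt.date(2018, 7, 1)], 2018)
        assert s.total == 1 and s.n_ignored == 1

    def test_conservation_by_year(self):
        rng = np.random.default_rng(0)
        dates = [dt.date(2017, 7, 1) + dt.timedelta(days=int(x)) for x in rng.integers(0, 1095, 500)]
        series, excluded = split_austral_years(dates, min_fish=1)
        assert sum(s.total for s in series.values()) == 500

    def test_thin_years_excluded(self):
        dates = [dt.date(2017, 8, 1)] * 40 + [dt.date(2019, 8, 1)] * 5
        series, excluded = split_austral_years(dates, min_fish=30)
        assert list(series) == [2017]
        assert excluded == {2019: 5}


class TestSpawningSmooth:
    def test_flat_series_recovers_constant(self):
        s = bin_hatch_dates([], 2018)
        s.counts = np.full(73, 7)
        fit = fit_spawning_smooth(s, k_grid=K_GRID, p_grid=P_GRID)
        assert fit.intercept_beta0 == pytest.approx(np.log(7), abs=0.05)
        assert fit.edf_terms["s(time)"] < 1.5  # smooth shrinks away
        assert detect_peaks(fit, s) == []

    def test_strong_single_cohort_explains_most_deviance(self):
        s = _year_series([(dt.date(2020, 11, 27), 20.0, 1.0)], 300, seed=1)
        fit = fit_spawning_smooth(s, k_grid=K_GRID, p_grid=P_GRID)
        assert fit.deviance_explained >= 0.8
        assert 1.0 < fit.tweedie_power_p < 2.0

    def test_doubling_counts_shifts_intercept_by_log2(self):
        """Log-link equivariance: at fixed smoothing parameters, scaling the
        counts moves only the intercept; the smooth shape is unchanged."""
        from reefspawn.smoothing import SplineTerm, fit_tweedie_gam

        rng = np.random.default_rng(2)
        x = np.arange(73) * 5.0 + 2.5
        # strictly positive counts: quasi-separation in all-zero stretches
        # would otherwise leave the intercept ill-determined
        y = 1.0 + rng.poisson(2 + 18 * np.exp(-0.5 * ((x - 150) / 35) ** 2))
        kwargs = dict(p_grid=np.array([1.5]), lambda_grids=[[10.0]], refine_p=False)
        fit1 = fit_tweedie_gam(y, [SplineTerm(k=12, name="s(t)")], [x], **kwargs)
        fit2 = fit_tweedie_gam(2 * y, [SplineTerm(k=12, name="s(t)")], [x], **kwargs)
        assert fit2.intercept_beta0 - fit1.intercept_beta0 == pytest.approx(np.log(2), abs=0.02)
        # shape near-unchanged (penalization is not exactly scale-equivariant:
        # the IRLS weights grow with the mean, slightly relaxing the smooth)
        ratio = fit2.fitted / fit1.fitted
        assert np.max(np.abs(np.log(ratio / 2.0))) < 0.1

    def test_fitted_mass_matches_total_count(self):
        s = _year_series([(dt.date(2020, 12, 12), 25.0, 1.0)], 500, seed=3)
        fit = fit_spawning_smooth(s, k_grid=K_GRID, p_grid=P_GRID)
        assert fit.fitted.sum() == pytest.approx(s.total, rel=0.05)

    def test_too_few_bins_raise(self):
        s = bin_hatch_dates([], 2018)
        s.counts = s.counts[:10]
        with pytest.raises(ValueError):
            fit_spawning_smooth(s)


class TestDetectPeaks:
    def test_single_cohort_peak_at_true_mode(self):
        s = _year_series([(dt.date(2020, 11, 27), 20.0, 1.0)], 300, seed=4)
        fit = fit_spawning_smooth(s, k_grid=K_GRID, p_grid=P_GRID)
        peaks = detect_peaks(fit, s, seed=4)
        assert len(peaks) == 1
        true_day = (dt.date(2020, 11, 27) - dt.date(2020, 7, 1)).days
        assert abs(peaks[0].day_of_year - true_day) <= 5
        lo, hi = peaks[0].ci95
        assert lo <= peaks[0].height <= hi

    def test_peak_agrees_with_grid_argmax(self):
        s = _year_series([(dt.date(2021, 1, 9), 18.0, 1.0)], 400, seed=5)
        fit = fit_spawning_smooth(s, k_grid=K_GRID, p_grid=P_GRID)
        peaks = detect_peaks(fit, s, seed=5)
        grid = np.arange(0.0, 365.0)
        argmax_day = grid[np.argmax(fit.predict([grid]))]
        assert len(peaks) == 1
        assert abs(peaks[0].day_of_year - argmax_day) <= 1

    def test_two_cohorts_two_peaks_with_correct_separation(self):
        s = _year_series(
            [(dt.date(2020, 11, 1), 12.0, 1.0), (dt.date(2021, 2, 9), 12.0, 1.0)], 500, seed=6
        )
        fit = fit_spawning_smooth(s, k_grid=K_GRID, p_grid=P_GRID)
        peaks = detect_peaks(fit, s, seed=6)
        assert len(peaks) == 2
        sep = peaks[1].day_of_year - peaks[0].day_of_year
        assert abs(sep - 100) <= 7

    def test_boundary_maxima_excluded(self):
        s = _year_series([(dt.date(2020, 7, 3), 8.0, 1.0)], 300, seed=7)
        fit = fit_spawning_smooth(s, k_grid=K_GRID, p_grid=P_GRID)
        for p in detect_peaks(fit, s, seed=7):
            assert 10 <= p.day_of_year <= 355


class TestSummarize:
    def test_two_peak_year_tabulated(self):
        s = _year_series(
            [(dt.date(2020, 10, 9), 10.0, 1.0), (dt.date(2021, 1, 17), 10.0, 1.0)], 500, seed=8
        )
        fit = fit_spawning_smooth(s, k_grid=K_GRID, p_grid=P_GRID)
        peaks = detect_peaks(fit, s, seed=8)
        table = summarize_peaks({2020: peaks}, {2020: fit})
        row = table.iloc[0]
        assert row["n_peaks"] == 2
        assert row["separations_days"][0] == pytest.approx(100, abs=7)
        assert row["mean_activity_per_bin"] > 0

    def test_empty_summary_is_valid(self):
        table = summarize_peaks({2020: []})
        assert table.iloc[0]["n_peaks"] == 0
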