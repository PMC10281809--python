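import datetime as dt

import numpy as np
import pandas as pd
import pytest

from reefspawn.agelength import (
    MARGINAL,
    assign_cohort,
    define_cohorts,
    fit_age_length,
    predict_age,
)
from reefspawn.synthetic import SpawningRegime, sample_hatch_dates

TRUE_BETA = np.array([-20.0, 1.2, -0.002, 0.000004])


def _cubic_age(tl):
    return np.vander(np.asarray(tl, dtype=float), 4, increasing=True) @ TRUE_BETA


def _two_cohort_frame(seed, n=600, cohort_shift=(-4.0, 4.0), noise="het"):
    rng = np.random.default_rng(seed)
    h1 = [dt.date(2020, 11, 1) + dt.timedelta(days=int(d)) for d in rng.integers(0, 40, n // 2)]
    h2 = [dt.date(2021, 2, 20) + dt.timedelta(days=int(d)) for d in rng.integers(0, 40, n - n // 2)]
    tl = rng.uniform(30, 240, n)
    shift = np.r_[np.full(n // 2, cohort_shift[0]), np.full(n - n // 2, cohort_shift[1])]
    if noise == "het":
        sd = np.exp(0.5 * (1.0 + 0.008 * (tl - 130)))
    elif noise == "none":
        sd = 0.0
    else:
        sd = float(noise)
    age = _cubic_age(tl) + shift + rng.normal(0, 1, n) * sd
    return pd.DataFrame(
        {
            "total_length_mm": tl,
            "post_settlement_age_days": np.maximum(age, 3.0),
            "hatch_date": h1 + h2,
        }
    )


class TestDefineCohorts:
    def test_two_modes_split(self):
        rng = np.random.default_rng(0)
        d1 = [dt.date(2020, 10, 1) + dt.timedelta(days=int(x)) for x in rng.integers(0, 20, 50)]
        d2 = [dt.date(2021, 1, 29) + dt.timedelta(days=int(x)) for x in rng.integers(0, 20, 50)]
        wins = define_cohorts(d1 + d2, gap_days=30)
        assert len(wins) == 2
        assert wins[0].end_date < wins[1].start_date

    def test_six_component_regime_recovered(self):
        # tight pulses, well separated relative to the 30-day gap rule
        comps = [(dt.date(2019, 7, 15) + dt.timedelta(days=60 * i), 3.0, 1.0) for i in range(6)]
        regime = SpawningRegime(comps, 0.0, (dt.date(2019, 7, 1), dt.date(2020, 6, 30)))
        dates = sample_hatch_dates(regime, 600, seed=8)
        wins = define_cohorts(dates, gap_days=30)
        assert len(wins) == 6

    def test_single_date(self):
        wins = define_cohorts([dt.date(2020, 1, 1)])
        assert len(wins) == 1 and wins[0].start_date == wins[0].end_date

    def test_windows_ordered_nonoverlapping(self):
        rng = np.random.default_rng(1)
        dates = [dt.date(2020, 7, 1) + dt.timedelta(days=int(x)) for x in rng.integers(0, 330, 200)]
        wins = define_cohorts(dates, gap_days=10)
        for a, b in zip(wins, wins[1:]):
            assert a.end_date < b.start_date


class TestFitAgeLength:
    def test_noise_free_recovers_cubic(self):
        """In the interpolation limit the fixed cubic is recovered to 4
        significant figures."""
        df = _two_cohort_frame(seed=2, noise=1e-4, cohort_shift=(0.0, 0.0))
        wins = define_cohorts(df["hatch_date"])
        fit = fit_age_length(df, wins)
        np.testing.assert_allclose(fit.fixed_coefficients, TRUE_BETA, rtol=5e-4)

    def test_recovers_cohort_effects_and_dispersion_sign(self):
        df = _two_cohort_frame(seed=3)
        wins = define_cohorts(df["hatch_date"])
        fit = fit_age_length(df, wins)
        effs = fit.cohort_effects
        assert effs["C1"] < -2 and effs["C2"] > 2
        assert abs(sum(effs.values())) < 1.0  # effects centred near zero
        assert fit.dispersion_coefficients["tl_slope"] > 0  # variance grows with TL
        assert 2 < fit.cohort_sd < 8

    def test_identical_cohorts_collapse_random_effect(self):
        df = _two_cohort_frame(seed=4, cohort_shift=(0.0, 0.0), noise=2.0)
        wins = define_cohorts(df["hatch_date"])
        fit = fit_age_length(df, wins)
        assert fit.cohort_sd < 1.0

    def test_too_few_cohorts_raise(self):
        df = _two_cohort_frame(seed=5).iloc[:10]
        df = df.assign(hatch_date=[dt.date(2020, 11, 5)] * 10)
        with pytest.raises(ValueError):
            fit_age_length(df, define_cohorts(df["hatch_date"]))


class TestAssignCohort:
    @pytest.fixture()
    def windows(self):
        return define_cohorts(
            [dt.date(2020, 11, 1), dt.date(2020, 12, 1), dt.date(2021, 3, 1), dt.date(2021, 3, 20)]
        )

    def test_inside_one_interval(self, windows):
        # C1 catchable between Nov 1 + 28 + 30 and Dec 1 + 28 + 90
        assert assign_cohort(dt.date(2021, 1, 15), windows, (30, 90), 28) == "C1"

    def test_outside_all_intervals(self, windows):
        assert assign_cohort(dt.date(2020, 8, 1), windows, (30, 90), 28) == MARGINAL

    def test_tie_goes_to_earlier_cohort(self):
        wins = define_cohorts([dt.date(2020, 11, 1), dt.date(2021, 1, 1)], gap_days=30)
        # wide age range makes both intervals cover the midpoint date
        mid = dt.date(2020, 12, 1) + dt.timedelta(days=28 + 100)
        assert assign_cohort(mid, wins, (10, 190), 28) == "C1"


@pytest.fixture(scope="module")
def fitted():
    df = _two_cohort_frame(seed=6)
    wins = define_cohorts(df["hatch_date"])
    return fit_age_length(df, wins)


class TestPredictAge:
    def test_noise_free_prediction_matches_curve(self):
        df = _two_cohort_frame(seed=7, noise=1e-4, cohort_shift=(0.0, 0.0))
        fit = fit_age_length(df, define_cohorts(df["hatch_date"]))
        for tl in (60.0, 120.0, 200.0):
            mean, _ = predict_age(fit, tl)
            assert mean == pytest.approx(float(_cubic_age([tl])[0]), rel=1e-3)

    def test_cohort_prediction_offsets_marginal(self, fitted):
        m_marg, _ = predict_age(fitted, 150.0, MARGINAL)
        m_c2, _ = predict_age(fitted, 150.0, "C2")
        assert m_c2 - m_marg == pytest.approx(fitted.cohort_effects["C2"], abs=0.5)

    def test_interval_widens_with_length(self, fitted):
        _, (lo1, hi1) = predict_age(fitted, 60.0, "C1")
        _, (lo2, hi2) = predict_age(fitted, 230.0, "C1")
        assert (hi2 - lo2) > (hi1 - lo1)  # dispersion slope > 0

    def test_out_of_range_refuses(self, fitted):
        with pytest.raises(ValueError):
            predict_age(fitted, 400.0)

    def test_mean_curve_monotone_over_observed_range(self, fitted):
        lo, hi = fitted.length_range
        grid = np.linspace(lo, hi, 150)
        assert np.all(np.diff(fitted.mean_curve(grid)) > -1e-6)
        assert np.all(fitted.mean_curve(grid) > 0)
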