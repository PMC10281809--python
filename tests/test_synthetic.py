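import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reefspawn.synthetic import (
    AgeingErrorModel,
    GrowthModel,
    SpawningRegime,
    draw_pld_counts,
    generate_env_series,
    realize_fish,
    sample_hatch_dates,
    simulate_study,
)


class TestSampleHatchDates:
    def test_single_component_mean(self):
        """Symmetric truncation leaves the truncated-normal mean at the peak."""
        regime = SpawningRegime(
            components=[(dt.date(2020, 12, 1), 10.0, 1.0)],
            background_rate=0.0,
            date_range=(dt.date(2020, 7, 1), dt.date(2021, 6, 30)),
        )
        dates = sample_hatch_dates(regime, 1000, seed=1)
        mean_day = np.mean([d.toordinal() for d in dates])
        assert abs(mean_day - dt.date(2020, 12, 1).toordinal()) < 2

    def test_background_only_uniform(self):
        regime = SpawningRegime(
            components=[], background_rate=10.0,
            date_range=(dt.date(2021, 10, 1), dt.date(2021, 12, 31)),
        )
        dates = sample_hatch_dates(regime, 920, seed=2)
        counts = pd.Series(dates).value_counts().reindex(
            [dt.date(2021, 10, 1) + dt.timedelta(days=i) for i in range(92)], fill_value=0
        )
        assert stats.chisquare(counts).pvalue > 0.001

    def test_determinism(self):
        regime = SpawningRegime(components=[(dt.date(2020, 12, 1), 10.0, 1.0)])
        assert sample_hatch_dates(regime, 100, seed=7) == sample_hatch_dates(regime, 100, seed=7)

    def test_empty_regime_rejected(self):
        with pytest.raises(ValueError):
            SpawningRegime(components=[], background_rate=0.0)

    def test_histogram_converges_to_mixture(self, bimodal_regime):
        """KS distance between the sample and the mixture CDF at n=5000."""
        dates = sample_hatch_dates(bimodal_regime, 5000, seed=3)
        lo, hi = bimodal_regime.date_range
        span = (hi - lo).days + 1
        obs = np.array([(d - lo).days for d in dates]) + 0.5

        grid = np.arange(span + 1, dtype=float)
        cdf = np.zeros_like(grid)
        for peak, spread, w in bimodal_regime.components:
            mu = (peak - lo).days
            a, b = (0 - mu) / spread, (span - 1 - mu) / spread
            cdf += 0.5 * stats.truncnorm.cdf(grid, a, b, loc=mu, scale=spread)
        ks = stats.ks_1samp(obs, lambda x: np.interp(x, grid, cdf)).statistic
        assert ks < 0.05


class TestRealizeFish:
    def test_zero_count_noise_gives_exact_replicates(self, small_fish_table):
        fish, _ = small_fish_table
        aged = fish[fish["count1"].notna()]
        assert (aged["count1"] == aged["true_age_days"]).all()
        assert (aged["count1"] == aged["count2"]).all()
        assert (aged["count2"] == aged["count3"]).all()

    def test_noiseless_length_monotone_in_age_within_trip(self, small_fish_table):
        fish, _ = small_fish_table
        for _, trip in fish.groupby("collection_date"):
            s = trip.sort_values("true_age_days")
            assert s["total_length_mm"].is_monotonic_increasing or len(s) < 2

    def test_aged_count_binomial_and_reproducible(self, bimodal_regime, noiseless_models):
        growth, error = noiseless_models
        hatches = sample_hatch_dates(bimodal_regime, 1000, seed=4)
        trips = [dt.date(2021, 5, 1), dt.date(2021, 8, 1)]
        fish1, r1 = realize_fish(hatches, growth, error, trips, seed=9, aged_fraction=0.43)
        fish2, r2 = realize_fish(hatches, growth, error, trips, seed=9, aged_fraction=0.43)
        assert r1["n_aged"] == r2["n_aged"]  # fixed seed -> exact count
        pd.testing.assert_frame_equal(fish1, fish2)
        n = r1["n_collected"]
        sd = np.sqrt(n * 0.43 * 0.57)
        assert abs(r1["n_aged"] - 0.43 * n) < 4 * sd

    def test_fish_dropped_when_no_trip_admits(self, noiseless_models):
        growth, error = noiseless_models
        hatches = [dt.date(2020, 1, 1)]
        # trip two days later: not yet settled (PLD 28 d)
        _, report = realize_fish(hatches, growth, error, [dt.date(2020, 1, 3)], seed=1)
        assert report["n_dropped"] == 1 and report["n_collected"] == 0

    def test_trip_before_hatch_raises(self, noiseless_models):
        growth, error = noiseless_models
        with pytest.raises(ValueError):
            realize_fish([dt.date(2021, 1, 1)], growth, error, [dt.date(2020, 12, 1)], seed=1)


class TestGrowthModel:
    def test_lengths_in_observed_range(self):
        g = GrowthModel()
        ages = np.arange(1, 510)
        lengths = g.length_at_age(ages)
        assert lengths.min() >= 23.0 and lengths.max() <= 248.0 * 1.05
        assert np.all(np.diff(lengths) > 0)

    def test_age_length_inverse(self):
        g = GrowthModel()
        ages = np.linspace(5, 400, 50)
        np.testing.assert_allclose(g.age_at_length(g.length_at_age(ages)), ages, rtol=1e-10)


class TestEnvSeries:
    def test_constant_when_noise_and_amplitude_zero(self):
        env = generate_env_series(
            (dt.date(2020, 1, 1), dt.date(2020, 3, 1)), seed=1,
            sst_amplitude_C=0.0, sst_noise_sd_C=0.0,
        )
        assert env["sst_C"].nunique() == 1
        assert (env["rainfall_mm"] >= 0).all()

    def test_peak_in_late_summer(self):
        env = generate_env_series(
            (dt.date(2020, 7, 1), dt.date(2021, 6, 30)), seed=1, sst_noise_sd_C=0.0
        )
        env["date"] = pd.to_datetime(env["date"])
        warm5 = env.set_index("date")["sst_C"].rolling(5).mean().idxmax()
        assert warm5.month in (1, 2)

    def test_no_missing_dates_and_reproducible(self):
        rng = (dt.date(2020, 1, 1), dt.date(2020, 12, 31))
        a = generate_env_series(rng, seed=5)
        b = generate_env_series(rng, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 366


def test_draw_pld_counts_distribution():
    counts = draw_pld_counts(AgeingErrorModel(), 5000, seed=1)
    assert abs(counts.mean() - 27.9) < 0.1
    assert abs(counts.std() - np.sqrt(1.6**2 + 1 / 12)) < 0.15


def test_simulate_study_structure():
    fish, env, report = simulate_study(seed=2, n_fish=400, start_years=(2018, 2019))
    assert report["n_collected"] == len(fish) <= 400
    assert fish["fish_id"].is_unique
    assert (fish["total_length_mm"] <= 250).all()
    assert env["date"].min() <= dt.date(2018, 7, 1)
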