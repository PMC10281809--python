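import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefspawn.closures import (
    SEASON_DAYS,
    ClosureWindow,
    capture_proportion,
    fit_capture_model,
    make_closures,
    new_moons,
    season_range,
)

SEASON_2021 = season_range(2021)
MOONS_2021 = new_moons(*SEASON_2021)


class TestMakeClosures:
    def test_three_nine_day_closures_close_27_days(self):
        wins = make_closures(MOONS_2021, 9, 3, SEASON_2021)
        assert sum(w.duration_days for w in wins) == 27

    def test_two_five_day_closures_close_10_days(self):
        wins = make_closures(MOONS_2021, 5, 2, SEASON_2021)
        assert sum(w.duration_days for w in wins) == 10
        # earliest moons selected first: October onward
        assert wins[0].anchor_new_moon.month == 10

    def test_duration_one_is_the_moon_date(self):
        wins = make_closures(MOONS_2021, 1, 1, SEASON_2021)
        assert wins[0].start_date == wins[0].end_date == MOONS_2021[0]

    def test_windows_centered(self):
        w = make_closures(MOONS_2021, 9, 1, SEASON_2021)[0]
        assert (w.anchor_new_moon - w.start_date).days == 4
        assert (w.end_date - w.anchor_new_moon).days == 4

    def test_too_many_closures_raise(self):
        with pytest.raises(ValueError):
            make_closures(MOONS_2021, 9, len(MOONS_2021) + 1, SEASON_2021)

    def test_overlapping_windows_merge(self):
        moons = [dt.date(2021, 10, 10), dt.date(2021, 10, 14)]
        with pytest.warns(UserWarning):
            wins = make_closures(moons, 9, 2, (dt.date(2021, 10, 1), dt.date(2021, 12, 31)))
        assert len(wins) == 1
        assert wins[0].start_date == dt.date(2021, 10, 6)
        assert wins[0].end_date == dt.date(2021, 10, 18)


class TestCaptureProportion:
    def test_uniform_activity_equals_closed_fraction(self):
        act = np.ones(SEASON_DAYS)
        for dur, n, days in ((9, 3, 27), (5, 2, 10)):
            wins = make_closures(MOONS_2021, dur, n, SEASON_2021)
            res = capture_proportion(act, wins, SEASON_2021)
            assert res.closed_days == days
            assert res.captured_proportion == res.expected_uniform == days / SEASON_DAYS

    def test_headline_capture_percentages(self):
        act = np.ones(SEASON_DAYS)
        r9 = capture_proportion(act, make_closures(MOONS_2021, 9, 3, SEASON_2021), SEASON_2021)
        r5 = capture_proportion(act, make_closures(MOONS_2021, 5, 2, SEASON_2021), SEASON_2021)
        assert round(100 * r9.captured_proportion) == 29
        assert round(100 * r5.captured_proportion) == 11

    def test_activity_only_inside_windows_captures_everything(self):
        wins = make_closures(MOONS_2021, 5, 2, SEASON_2021)
        act = np.zeros(SEASON_DAYS)
        for w in wins:
            for d in w.days():
                act[(d - SEASON_2021[0]).days] = 3.0
        res = capture_proportion(act, wins, SEASON_2021)
        assert res.captured_proportion == 1.0

    @given(scale=st.floats(1e-6, 1e6))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(1)
        act = rng.gamma(2.0, 1.0, SEASON_DAYS)
        wins = make_closures(MOONS_2021, 9, 2, SEASON_2021)
        a = capture_proportion(act, wins, SEASON_2021).captured_proportion
        b = capture_proportion(act * scale, wins, SEASON_2021).captured_proportion
        assert a == pytest.approx(b, rel=1e-9)

    def test_enlarging_window_never_decreases_capture(self):
        rng = np.random.default_rng(2)
        act = rng.gamma(2.0, 1.0, SEASON_DAYS)
        prev = 0.0
        for dur in (1, 3, 5, 7, 9, 15):
            wins = make_closures(MOONS_2021, dur, 3, SEASON_2021)
            cur = capture_proportion(act, wins, SEASON_2021).captured_proportion
            assert cur >= prev - 1e-12
            prev = cur

    def test_merged_overlap_counts_days_once(self):
        rng = np.random.default_rng(3)
        act = rng.gamma(2.0, 1.0, SEASON_DAYS)
        a = ClosureWindow(dt.date(2021, 10, 5), dt.date(2021, 10, 13), dt.date(2021, 10, 9))
        b = ClosureWindow(dt.date(2021, 10, 10), dt.date(2021, 10, 18), dt.date(2021, 10, 14))
        union = ClosureWindow(dt.date(2021, 10, 5), dt.date(2021, 10, 18), dt.date(2021, 10, 9))
        both = capture_proportion(act, [a, b], SEASON_2021)
        one = capture_proportion(act, [union], SEASON_2021)
        assert both.captured_proportion == pytest.approx(one.captured_proportion, abs=1e-12)
        assert both.closed_days == one.closed_days == 14

    def test_all_zero_activity_rejected(self):
        wins = make_closures(MOONS_2021, 9, 1, SEASON_2021)
        with pytest.raises(ValueError):
            capture_proportion(np.zeros(SEASON_DAYS), wins, SEASON_2021)


def _uniform_capture_frame(years=range(2016, 2021)):
    """Capture results computed from genuinely uniform activity in each
    year: variation across years comes only from moon placement/clipping."""
    rows = []
    for y in years:
        season = season_range(y)
        moons = new_moons(*season)
        act = np.ones(SEASON_DAYS)
        for dur in (5, 9):
            for n in (1, 2, 3):
                if n > len(moons):
                    continue
                wins = make_closures(moons, dur, n, season)
                res = capture_proportion(act, wins, season, year_label=y, duration_days=dur)
                rows.append(res.__dict__)
    return pd.DataFrame(rows)


class TestCaptureModel:
    def test_uniform_inputs_give_duration_ratio_nine_fifths(self):
        fit = fit_capture_model(_uniform_capture_frame())
        assert fit.duration_ratio == pytest.approx(9 / 5, rel=0.05)

    def test_closure_count_effect_monotone(self):
        fit = fit_capture_model(_uniform_capture_frame())
        preds = fit.predictions.set_index(["duration_days", "n_closures"])["predicted_capture"]
        for d in (5, 9):
            assert preds[d, 1] < preds[d, 2] < preds[d, 3]

    def test_all_equal_proportions_give_zero_slopes(self):
        rows = []
        for y in (2016, 2017, 2018):
            for d in (5, 9):
                for n in (1, 2):
                    rows.append(dict(year_label=y, duration_days=d, n_closures=n,
                                     captured_proportion=0.2))
        fit = fit_capture_model(pd.DataFrame(rows))
        assert abs(fit.coef["dur9"]) < 1e-3
        assert abs(fit.coef["n2"]) < 1e-3

    def test_requires_two_levels(self):
        df = _uniform_capture_frame()
        with pytest.raises(ValueError):
            fit_capture_model(df[df["duration_days"] == 9])

    def test_no_effect_simulation_keeps_coefficients_near_zero(self):
        """With capture independent of design, both effects stay within
        2 s.e. of zero in most replicates."""
        ok = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            rows = []
            for y in (2016, 2017, 2018, 2019):
                for d in (5, 9):
                    for n in (1, 2, 3):
                        rows.append(dict(year_label=y, duration_days=d, n_closures=n,
                                         captured_proportion=float(np.clip(
                                             0.2 * np.exp(rng.normal(0, 0.2)), 0.01, 0.9))))
            fit = fit_capture_model(pd.DataFrame(rows))
            good = all(
                abs(fit.coef[c]) <= 2 * fit.coef_se[c]
                for c in ("dur9", "n2", "n3")
                if np.isfinite(fit.coef_se[c])
            )
            ok += good
        assert ok >= int(0.7 * n_rep)
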