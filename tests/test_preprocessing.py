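"""Daily-yield assembly, the three filter rules, and the spline fit."""

import numpy as np
import pandas as pd
import pytest

from resilind.preprocessing import (FilterAudit, InputError,
                                    aggregate_daily_yields,
                                    build_lactation_series, filter_farm_days,
                                    fit_lactation_curve,
                                    remove_gap_adjacent_days,
                                    window_and_coverage_filter)
from tests.conftest import wood_yields


def _records(rows):
    return pd.DataFrame(rows, columns=["animal_id", "farm_id", "timestamp", "yield_kg"])


class TestAggregateDailyYields:
    def test_overnight_first_milking_split_proportionally(self):
        # previous milking 18:00 day D, first milking 06:00 day D+1 of 12 kg:
        # 6 of the 12 interval hours fall on each day -> 6 kg to each
        rec = _records([
            ("c1", "f1", "2020-03-01 18:00", 10.0),
            ("c1", "f1", "2020-03-02 06:00", 12.0),
        ])
        daily = aggregate_daily_yields(rec)
        d1 = daily.set_index(daily["date"].dt.strftime("%Y-%m-%d"))["yield_kg"]
        assert d1["2020-03-01"] == pytest.approx(10.0 + 6.0)
        assert d1["2020-03-02"] == pytest.approx(6.0)

    def test_midnight_milking_goes_wholly_to_previous_day(self):
        rec = _records([
            ("c1", "f1", "2020-03-01 20:00", 8.0),
            ("c1", "f1", "2020-03-02 00:00", 5.0),
        ])
        daily = aggregate_daily_yields(rec)
        d1 = daily.set_index(daily["date"].dt.strftime("%Y-%m-%d"))["yield_kg"]
        assert d1["2020-03-01"] == pytest.approx(13.0)
        assert "2020-03-02" not in d1.index or d1["2020-03-02"] == 0.0

    def test_first_milking_without_predecessor_stays_on_own_day(self):
        rec = _records([("c1", "f1", "2020-03-01 05:00", 9.0)])
        daily = aggregate_daily_yields(rec)
        assert len(daily) == 1
        assert daily.loc[0, "yield_kg"] == pytest.approx(9.0)
        assert daily.loc[0, "date"] == pd.Timestamp("2020-03-01")

    def test_mass_conservation_on_simulated_data(self, small_milkings):
        milkings, _, _ = small_milkings
        daily = aggregate_daily_yields(milkings)
        assert daily["yield_kg"].sum() == pytest.approx(milkings["yield_kg"].sum())

    def test_input_validation(self):
        with pytest.raises(InputError):
            aggregate_daily_yields(_records([("c1", "f1", "2020-03-01 05:00", -1.0)]))
        with pytest.raises(InputError):
            aggregate_daily_yields(_records([
                ("c1", "f1", "2020-03-01 05:00", 1.0),
                ("c1", "f1", "2020-03-01 05:00", 1.0),
            ]))


class TestFarmDayFilter:
    @staticmethod
    def _farm_days(counts, farm="f1"):
        """One row per animal per day; counts[k] animals on day k."""
        rows = []
        for k, c in enumerate(counts):
            date = pd.Timestamp("2020-01-01") + pd.Timedelta(days=k)
            for a in range(c):
                rows.append((f"a{a}", farm, date, 10.0))
        return pd.DataFrame(rows, columns=["animal_id", "farm_id", "date", "yield_kg"])

    def test_constant_counts_remove_nothing(self):
        daily = self._farm_days([50] * 20)
        out = filter_farm_days(daily)
        assert len(out) == len(daily)

    def test_outlier_day_removed_with_neighbours(self):
        rng = np.random.default_rng(0)
        counts = list(49 + rng.integers(0, 3, size=30))  # mean ~50, small SD
        counts[10] = 20  # far beyond 3 SD
        daily = self._farm_days(counts)
        out = filter_farm_days(daily)
        removed_days = set(daily["date"]) - set(out["date"])
        expected = {pd.Timestamp("2020-01-01") + pd.Timedelta(days=k) for k in (9, 10, 11)}
        assert removed_days == expected

    def test_threshold_is_inclusive_at_exactly_the_sd_limit(self):
        # counts [10]*8 + [4]: mean 9.333, SD 2.0, the low day sits at
        # exactly 8/3 SD below the mean; the rule fires at threshold == dev
        c = np.array([10] * 8 + [4])
        dev = abs(c[-1] - c.mean()) / c.std(ddof=1)
        assert dev == pytest.approx(8.0 / 3.0)
        daily = self._farm_days(list(c))
        at_threshold = filter_farm_days(daily, sd_threshold=float(dev))
        assert len(set(daily["date"]) - set(at_threshold["date"])) >= 1
        above_threshold = filter_farm_days(daily, sd_threshold=float(dev) * 1.001)
        assert len(above_threshold) == len(daily)

    def test_single_day_farm_skipped_with_warning(self, caplog):
        daily = self._farm_days([5])
        with caplog.at_level("WARNING"):
            out = filter_farm_days(daily)
        assert len(out) == len(daily)
        assert any("count filter skipped" in m for m in caplog.messages)


class TestGapAdjacentRemoval:
    def test_complete_series_unchanged(self):
        days = np.arange(1, 11)
        np.testing.assert_array_equal(remove_gap_adjacent_days(days), days)

    def test_single_missing_day_removes_neighbours(self):
        days = np.array([1, 2, 3, 4, 6, 7, 8, 9, 10])  # day 5 missing
        kept = remove_gap_adjacent_days(days)
        np.testing.assert_array_equal(kept, [1, 2, 3, 7, 8, 9, 10])

    def test_multi_day_gap_removes_one_neighbour_each_side(self):
        days = np.array([1, 2, 3, 7, 8])
        np.testing.assert_array_equal(remove_gap_adjacent_days(days), [1, 2, 8])

    def test_idempotent_given_observed_reference(self):
        days = np.array([1, 2, 3, 4, 6, 7, 8, 9, 10])
        once = remove_gap_adjacent_days(days)
        twice = remove_gap_adjacent_days(once, observed=days)
        np.testing.assert_array_equal(twice, once)

    def test_gap_at_window_start_removes_only_following_day(self):
        # data begins after a leading gap relative to the observed range
        days = np.array([4, 5, 6])
        kept = remove_gap_adjacent_days(days, observed=np.array([1, 4, 5, 6]))
        np.testing.assert_array_equal(kept, [5, 6])


class TestWindowCoverage:
    @staticmethod
    def _series(days):
        return pd.DataFrame({
            "animal_id": "c1", "lactation": 1, "day_in_milk": days,
            "yield_kg": 20.0, "farm_id": "f1",
            "date": pd.Timestamp("2020-01-01") + pd.to_timedelta(days, unit="D"),
        })

    def test_days_outside_window_dropped(self):
        out = window_and_coverage_filter(self._series(np.arange(0, 400)))
        assert out["day_in_milk"].min() == 10
        assert out["day_in_milk"].max() == 305
        assert len(out) == 296

    @pytest.mark.parametrize("n_days,kept", [(148, True), (147, False)])
    def test_retention_boundary_at_148_days(self, n_days, kept):
        out = window_and_coverage_filter(self._series(np.arange(10, 10 + n_days)))
        assert (len(out) > 0) == kept

    def test_idempotent(self, small_milkings):
        milkings, calvings, _ = small_milkings
        from resilind.preprocessing import aggregate_daily_yields, assign_lactations
        daily = assign_lactations(aggregate_daily_yields(milkings), calvings)
        once = window_and_coverage_filter(daily)
        twice = window_and_coverage_filter(once)
        pd.testing.assert_frame_equal(once, twice)


class TestLactationCurveFit:
    def test_interpolates_smooth_curve(self):
        # gently curved noise-free series, well within 5 df of smoothness
        days = np.arange(10, 306).astype(float)
        y = 28.0 - 0.025 * days + 3.0 * np.sin(days / 150.0)
        pred, w = fit_lactation_curve(days, y)
        assert np.max(np.abs(pred - y)) < 0.01 * (y.max() - y.min())
        assert np.all((w >= 0.1) & (w <= 1.0))

    def test_wood_curve_fit_is_unbiased_at_mid_lactation(self, smooth_lactation):
        # the steep early rise exceeds what 5 effective df can track, but
        # away from the boundary the noise-free fit should be close
        days, y = smooth_lactation
        pred, _ = fit_lactation_curve(days, y, n_reweight=0)
        mid = (days > 60) & (days < 280)
        assert np.max(np.abs(pred[mid] - y[mid])) < 0.02 * (y.max() - y.min())

    def test_cubic_polynomial_reproduced_exactly(self):
        days = np.arange(10, 306).astype(float)
        x = (days - days.mean()) / 100.0
        y = 1.0 + 0.5 * x - 0.3 * x ** 2 + 0.2 * x ** 3
        pred, _ = fit_lactation_curve(days, y)
        assert np.max(np.abs(pred - y)) < 1e-6

    def test_downweighting_tracks_baseline_through_drop(self, smooth_lactation):
        days, base = smooth_lactation
        y = base.copy()
        drop = slice(100, 110)  # 10-day 30% drop
        y[drop] = 0.7 * base[drop]
        pred, w = fit_lactation_curve(days, y)
        in_drop_pred = pred[drop].mean()
        assert abs(in_drop_pred - base[drop].mean()) < abs(in_drop_pred - y[drop].mean())
        assert w[drop].mean() < 0.9  # disturbance days were down-weighted

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_lactation_curve(np.arange(10), np.ones(10))


def test_full_chain_counts_on_constructed_fixture():
    """Hand-countable scenario: one cow with a mid-lactation gap."""
    rows = []
    calving = pd.Timestamp("2020-01-01")
    for d in range(1, 306):
        if d in (150, 151):  # two-day gap
            continue
        date = calving + pd.Timedelta(days=d)
        rows.append(("c1", "f1", date + pd.Timedelta(hours=6), 10.0))
        rows.append(("c1", "f1", date + pd.Timedelta(hours=18), 10.0))
    milkings = pd.DataFrame(rows, columns=["animal_id", "farm_id", "timestamp", "yield_kg"])
    calvings = pd.DataFrame({"animal_id": ["c1"], "lactation": [1],
                             "calving_date": [calving]})
    series, audit = build_lactation_series(milkings, calvings)
    # window has 296 days; gap removes 149+152 (numbers 2) leaving 296-4=292
    days = series["day_in_milk"].to_numpy()
    assert len(days) == 292
    assert {149, 150, 151, 152}.isdisjoint(days)
    assert audit.counts["coverage_filter"] == 0


def test_filters_applied_in_documented_order(small_milkings):
    milkings, calvings, _ = small_milkings
    series, audit = build_lactation_series(milkings, calvings)
    assert list(audit.counts) == ["input_days", "no_milking_days",
                                  "farm_day_filter", "gap_adjacent_filter",
                                  "window_filter", "coverage_filter"]
    # all retained lactations satisfy the window and coverage invariants
    grp = series.groupby(["animal_id", "lactation"])["day_in_milk"]
    assert grp.min().min() >= 10
    assert grp.max().max() <= 305
    assert grp.size().min() >= 148
    assert not series.duplicated(["animal_id", "lactation", "day_in_milk"]).any()
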