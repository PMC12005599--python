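"""Home inference, distance/bearing, windowed features, and change points."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ema_context import sensor_markers as sm

H = 3600.0


def _times(hours):
    """Clock hours on 2023-03-07 as epoch-second floats (UTC semantics)."""
    base = np.datetime64("2023-03-07T00:00:00").astype("datetime64[s]").astype(float)
    return base + np.asarray(hours, float) * H


def _dt(hours):
    import pandas as pd

    return pd.to_datetime(_times(hours), unit="s")


class TestInferHome:
    def test_single_cluster(self):
        t = _dt([3, 4, 5])
        home = sm.infer_home(t, [46.7301] * 3, [-117.17] * 3)
        assert home.latitude == pytest.approx(46.7301)
        assert home.longitude == pytest.approx(-117.17)
        assert home.support_count == 3

    def test_modal_cell_wins_counting_oracle(self):
        """10 fixes at A vs 3 at B: A's centroid wins by the cell vote."""
        lat = [46.7301] * 10 + [46.8000] * 3
        lon = [-117.1700] * 10 + [-117.3000] * 3
        t = _dt(np.linspace(2.1, 8.9, 13))
        home = sm.infer_home(t, lat, lon)
        assert home.support_count == 10
        assert home.latitude == pytest.approx(46.7301, abs=1e-6)

    def test_only_night_fixes_count(self):
        # daytime cluster is bigger but outside the 2-9 AM window
        lat = [46.9] * 20 + [46.7] * 2
        lon = [-117.9] * 20 + [-117.1] * 2
        t = _dt([12] * 20 + [3, 4])
        home = sm.infer_home(t, lat, lon)
        assert home.latitude == pytest.approx(46.7)

    def test_no_night_fixes_is_an_error(self):
        with pytest.raises(sm.HomeUndeterminableError):
            sm.infer_home(_dt([10, 12, 22]), [46.7] * 3, [-117.1] * 3)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        hours = np.linspace(2.1, 8.9, 40)
        lat = 46.73 + rng.normal(0, 1e-5, 40)
        lon = -117.17 + rng.normal(0, 1e-5, 40)
        perm = rng.permutation(40)
        a = sm.infer_home(_dt(hours), lat, lon)
        b = sm.infer_home(_dt(hours[perm]), lat[perm], lon[perm])
        assert (a.latitude, a.longitude, a.support_count) == (
            b.latitude,
            b.longitude,
            b.support_count,
        )


class TestDistanceBearing:
    def test_coincident_points(self):
        assert sm.distance_bearing(46.7, -117.1, 46.7, -117.1) == (0.0, 0.0)

    def test_one_degree_north_at_equator(self):
        d, b = sm.distance_bearing(0.0, 0.0, 1.0, 0.0)
        # haversine closed form: R * pi/180
        assert d == pytest.approx(sm.EARTH_RADIUS_M * math.pi / 180, rel=1e-9)
        assert b == pytest.approx(0.0)

    def test_one_degree_east_at_equator(self):
        d, b = sm.distance_bearing(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(111_195, rel=1e-3)
        assert b == pytest.approx(90.0)

    def test_bearing_quadrants(self):
        _, b = sm.distance_bearing(0.0, 0.0, -1.0, 0.0)
        assert b == pytest.approx(180.0)
        _, b = sm.distance_bearing(0.0, 0.0, 0.0, -1.0)
        assert b == pytest.approx(270.0)


HOME = sm.HomeLocation(latitude=46.73, longitude=-117.17, support_count=1)
FAR = 46.73 + 0.01  # ~1.1 km north of home


class TestAtHomeFraction:
    def test_all_fixes_at_home(self):
        t = _times(np.arange(10, 10.6, 1 / 12))  # every 5 min
        frac = sm.at_home_fraction(t, [46.73] * len(t), [-117.17] * len(t), HOME, _times(10.5))
        assert frac == 1.0

    def test_half_home_half_away(self):
        """15 min at home then 15 min away inside the 30-min window."""
        t = _times([10.0, 10.25, 10.5])
        lat = [46.73, FAR, FAR]
        lon = [-117.17] * 3
        frac = sm.at_home_fraction(t, lat, lon, HOME, _times(10.5))
        assert frac == pytest.approx(0.5)

    def test_hand_labeled_interval_fixture(self):
        """7 fixes at 5-min spacing: intervals labeled by their starting fix."""
        t = _times(10 + np.arange(7) / 12)  # 10:00 .. 10:30
        at_home = [True, True, False, False, True, True, True]
        lat = [46.73 if h else FAR for h in at_home]
        lon = [-117.17] * 7
        # home-labeled time: intervals 1,2 (10 min) + 5,6 (10 min) + last fix->t (0)
        frac = sm.at_home_fraction(t, lat, lon, HOME, _times(10.5))
        assert frac == pytest.approx(20.0 / 30.0)

    def test_carry_forward_before_window(self):
        t = _times([9.0])  # 60 min before the window end, within staleness
        frac = sm.at_home_fraction(t, [46.73], [-117.17], HOME, _times(10.5))
        assert frac == 1.0

    def test_unavailable_without_fixes(self):
        assert np.isnan(sm.at_home_fraction(_times([12.0]), [46.73], [-117.17], HOME, _times(10.5)))
        stale = sm.at_home_fraction(_times([1.0]), [46.73], [-117.17], HOME, _times(10.5))
        assert np.isnan(stale)  # beyond the 2 h staleness limit

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.booleans(), min_size=1, max_size=12), st.integers(0, 30))
    def test_fraction_bounded(self, labels, offset_min):
        t = _times(10 + np.arange(len(labels)) / 20)
        lat = [46.73 if h else FAR for h in labels]
        frac = sm.at_home_fraction(
            t, lat, [-117.17] * len(labels), HOME, _times(10.0) + offset_min * 60
        )
        assert np.isnan(frac) or 0.0 <= frac <= 1.0


class TestActivityLevel:
    def test_zero_magnitudes(self):
        t = _times(10 + np.arange(30) / 60.0)
        assert sm.activity_level_watch(t, np.zeros(30), _times(10.5)) == 0.0

    def test_constant_signal_per_minute_rate(self):
        """Constant magnitude 1 at 1 sample/min gives 1 per minute."""
        t = _times(10 + np.arange(1, 31) / 60.0)  # 10:01 .. 10:30
        level = sm.activity_level_watch(t, np.ones(30), _times(10.5))
        assert level == pytest.approx(1.0)

    def test_known_sum_fixture(self):
        rng = np.random.default_rng(3)
        mags = rng.uniform(0, 2, 30)
        t = _times(10 + np.arange(1, 31) / 60.0)
        level = sm.activity_level_watch(t, mags, _times(10.5))
        assert level == pytest.approx(mags.sum() / 30.0)

    def test_covered_but_empty_window_is_zero(self):
        t = _times([8.0, 12.0])
        assert sm.activity_level_watch(t, [1.0, 1.0], _times(10.0)) == 0.0

    def test_uncovered_window_is_unavailable(self):
        t = _times([12.0])
        assert np.isnan(sm.activity_level_watch(t, [1.0], _times(10.0)))

    def test_ambient_motion_count_with_boundaries(self):
        """Only events strictly inside (t-30min, t] are counted."""
        t_end = _times(10.5)
        offsets = np.array([-30.0, -29.9, -15.0, -0.001, 0.0, 0.5]) * 60
        ev = sm.AmbientEvents(
            times=t_end + offsets,
            kinds=np.array(["motion"] * 6, object),
            states=np.array(["on"] * 6, object),
            sensor_ids=np.array(["m1"] * 6, object),
        )
        # -30 exactly is outside the half-open window; +0.5 min is after t
        assert sm.activity_level_ambient(ev, t_end) == 4.0
        ev_off = sm.AmbientEvents(
            times=ev.times,
            kinds=ev.kinds,
            states=np.array(["off"] * 6, object),
            sensor_ids=ev.sensor_ids,
        )
        assert sm.activity_level_ambient(ev_off, t_end) == 0.0


def _ambient(rows):
    rows = sorted(rows)
    return sm.AmbientEvents(
        times=np.array([r[0] for r in rows], float),
        kinds=np.array([r[1] for r in rows], object),
        states=np.array([r[2] for r in rows], object),
        sensor_ids=np.array(["x"] * len(rows), object),
    )


class TestOutOfHome:
    def test_quick_return_motion_means_no_interval(self):
        ev = _ambient(
            [
                (_times(10.0), "door", "open"),
                (_times(10.0) + 30, "door", "closed"),
                (_times(10.0) + 150, "motion", "on"),  # 2 min later
            ]
        )
        assert sm.out_of_home_intervals(ev) == []

    def test_long_silence_then_motion(self):
        close = _times(10.0) + 30
        back = _times(11.0)  # 60 min of silence
        ev = _ambient(
            [
                (_times(9.5), "motion", "on"),
                (_times(10.0), "door", "open"),
                (close, "door", "closed"),
                (back, "motion", "on"),
            ]
        )
        assert sm.out_of_home_intervals(ev) == [(close, back)]

    def test_no_door_events(self):
        ev = _ambient([(_times(9.0), "motion", "on"), (_times(9.5), "motion", "on")])
        assert sm.out_of_home_intervals(ev) == []

    def test_unmatched_open_treated_as_departure(self):
        ev = _ambient(
            [
                (_times(9.0), "motion", "on"),
                (_times(10.0), "door", "open"),
                (_times(12.0), "motion", "on"),  # return, 2 h later
            ]
        )
        with pytest.warns(UserWarning, match="unmatched"):
            intervals = sm.out_of_home_intervals(ev)
        assert intervals == [(_times(10.0), _times(12.0))]

    def test_intervals_disjoint_and_never_cover_motion(self, ambient_dataset):
        assert any(p.ambient is not None for p in ambient_dataset.participants)
        for p in ambient_dataset.participants:
            if p.ambient is None:
                continue
            intervals = sm.out_of_home_intervals(p.ambient)
            for (a0, b0), (a1, b1) in zip(intervals, intervals[1:]):
                assert b0 <= a1
            motion = p.ambient.motion_on_times()
            for a, b in intervals:
                assert not np.any((motion > a) & (motion < b))


def _exhaustive_partition(x, penalty):
    """Independent oracle: optimal segmentation by plain Bellman recursion
    over every admissible last-segment start (no pruning)."""
    x = np.asarray(x, float)
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(s, t):
        d = cs[t] - cs[s]
        return cs2[t] - cs2[s] - d * d / (t - s)

    F = [0.0] * (n + 1)
    F[0] = -penalty
    arg = [0] * (n + 1)
    for t in range(1, n + 1):
        best, bs = math.inf, 0
        for s in range(t):
            v = F[s] + cost(s, t) + penalty
            if v < best:
                best, bs = v, s
        F[t], arg[t] = best, bs
    bps, t = [], n
    while t > 0:
        if arg[t] > 0:
            bps.append(arg[t])
        t = arg[t]
    return bps[::-1]


class TestChangePoints:
    def test_constant_series_has_no_change_points(self):
        assert sm.detect_change_points(np.ones(50), penalty=1.0) == []

    def test_single_step_recovered(self):
        rng = np.random.default_rng(1)
        x = np.r_[np.zeros(100), np.full(100, 10.0)] + rng.normal(0, 0.1, 200)
        cps = sm.detect_change_points(x)
        assert len(cps) == 1
        assert abs(cps[0] - 100) <= 2

    def test_two_equal_steps_recovered(self):
        rng = np.random.default_rng(2)
        x = np.r_[np.zeros(10), np.full(10, 5.0), np.zeros(10)] + rng.normal(0, 0.1, 30)
        cps = sm.detect_change_points(x, penalty=1.0)
        assert cps == _exhaustive_partition(x, 1.0)
        assert cps == [10, 20]

    def test_short_series_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter than 4"):
            assert sm.detect_change_points(np.array([1.0, 2.0, 3.0])) == []

    def test_engines_agree(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 300) + np.repeat(rng.normal(0, 3, 6), 50)
        pen = sm.default_penalty(x)
        ref = sm.pelt_mean_shift(x, pen, engine="numpy")
        assert sm.pelt_mean_shift(x, pen) == ref

    def test_timestamps_returned_when_given(self):
        x = np.r_[np.zeros(20), np.full(20, 8.0)]
        times = _times(np.arange(40) / 60.0)
        cps = sm.detect_change_points(x, penalty=1.0, times=times)
        assert cps and cps[0] == times[20]


class TestCpNearness:
    def test_at_change_point(self):
        assert sm.cp_nearness(_times(10.0), [_times(10.0)]) == 1.0

    def test_one_tau_away(self):
        t = _times(10.0)
        assert sm.cp_nearness(t + 15 * 60, [t], tau_min=15) == pytest.approx(
            math.exp(-1)
        )

    def test_no_change_points_far_sentinel(self):
        assert sm.cp_nearness(_times(10.0), []) == 0.0

    def test_nearest_wins(self):
        t = _times(10.0)
        cps = [t - 3600, t + 300]
        assert sm.cp_nearness(t, cps, tau_min=15) == pytest.approx(math.exp(-5 / 15))


class TestGroundTruthRecovery:
    def test_home_recovered_within_50_m(self, mini_dataset):
        import pandas as pd

        for p in mini_dataset.participants:
            if p.ambient is not None:
                continue
            home = sm.infer_home(
                pd.to_datetime(p.fix_times, unit="s"), p.fix_lat, p.fix_lon
            )
            d, _ = sm.distance_bearing(
                home.latitude, home.longitude, p.truth.home_lat, p.truth.home_lon
            )
            assert d <= 50.0

    def test_away_bouts_recovered_within_5_min(self, ambient_dataset):
        found = 0
        total = 0
        for p in ambient_dataset.participants:
            if p.ambient is None:
                continue
            detected = sm.out_of_home_intervals(p.ambient)
            for a, b in p.truth.away_intervals:
                total += 1
                if any(abs(a - da) <= 300 and abs(b - db) <= 300 for da, db in detected):
                    found += 1
        assert total > 0
        assert found / total >= 0.9

    def test_transitions_detected_on_binned_activity(self, mini_dataset):
        """Most true activity transitions get a change point within 10 bins."""
        hits = 0
        total = 0
        for p in mini_dataset.participants[:6]:
            series = p.accel_mag[: (len(p.accel_mag) // 5) * 5].reshape(-1, 5).mean(axis=1)
            bin_times = p.accel_times[:: 5][: len(series)]
            cps = np.array(
                sm.detect_change_points(series, times=bin_times), float
            )
            for t in p.truth.transitions:
                total += 1
                if cps.size and np.min(np.abs(cps - t)) <= 10 * 300:
                    hits += 1
        assert hits / total >= 0.9
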