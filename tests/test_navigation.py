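"""Homing metrics on hand-built translocation records."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from frognav.core import DistanceClass, Fix, TranslocationRecord, Trajectory
from frognav.navigation import (NavConfig, angular_deviation, explored_area,
                                homing_duration, homing_success,
                                normalize_homeward, straightness,
                                summarize_navigation)

from conftest import square_home, translocation, traj


class TestHomingSuccess:
    def test_72_percent_approach_is_homing(self):
        rec = translocation([(10, 0), (36, 0)])
        assert homing_success(rec) is True

    def test_60_percent_approach_is_not(self):
        rec = translocation([(10, 0), (30, 0)])
        assert homing_success(rec) is False

    def test_window_boundary_inclusive(self):
        release_time = datetime(2023, 1, 1, 12, 0)
        home = square_home((50.0, 0.0))
        fixes = (Fix("a", release_time + timedelta(days=3), 50.0, 0.0),)
        rec = TranslocationRecord("a", (0.0, 0.0), release_time,
                                  DistanceClass.D50, home,
                                  Trajectory("a", fixes))
        assert homing_success(rec) is True
        late = (Fix("a", release_time + timedelta(days=3, minutes=1),
                    50.0, 0.0),)
        rec2 = TranslocationRecord("a", (0.0, 0.0), release_time,
                                   DistanceClass.D50, home,
                                   Trajectory("a", late))
        assert homing_success(rec2) is False

    def test_zero_translocation_distance_errors(self):
        rec = translocation([(10, 0)], home_center=(0.0, 0.0))
        with pytest.raises(ValueError, match="coincides"):
            homing_success(rec)

    def test_monotone_in_homing_fraction(self):
        # raising the threshold can only flip true -> false
        for frac_pts in [[(20, 0)], [(36, 0)], [(45, 0)], [(50, 0)]]:
            rec = translocation(frac_pts)
            prev = True
            for frac in (0.5, 0.6, 0.7, 0.8, 0.9):
                ok = homing_success(rec, NavConfig(homing_fraction=frac))
                assert prev or not ok
                prev = ok


class TestExploredArea:
    def test_single_fix_point_buffer(self):
        tr = traj([(0, 0)])
        assert explored_area(tr) == pytest.approx(math.pi * 25.0, rel=1e-3)

    def test_straight_segment_stadium(self):
        tr = traj([(0, 0), (100, 0)])
        expected = 2 * 5 * 100 + math.pi * 25.0
        assert explored_area(tr) == pytest.approx(expected, rel=5e-3)

    def test_out_and_back_same_as_one_way(self):
        one_way = explored_area(traj([(0, 0), (100, 0)]))
        there_and_back = explored_area(traj([(0, 0), (100, 0), (0, 0)]))
        assert there_and_back == pytest.approx(one_way, rel=1e-9)

    def test_monotone_under_added_fixes(self):
        base = explored_area(traj([(0, 0), (50, 0)]))
        more = explored_area(traj([(0, 0), (50, 0), (50, 40)]))
        assert more > base

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(-30, 30, size=(8, 2))
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)],
                        [np.sin(th), np.cos(th)]])
        moved = pts @ rot.T + np.array([500.0, -200.0])
        a1 = explored_area(traj(pts))
        a2 = explored_area(traj(moved))
        assert a2 == pytest.approx(a1, rel=1e-6)


class TestStraightness:
    def test_straight_path_is_one(self):
        rec = translocation([(10, 0), (20, 0), (36, 0)])
        assert straightness(rec) == pytest.approx(1.0)

    def test_dogleg_example(self):
        # (0,0) -> (3,4) -> (6,0): net 6, path 10
        rec = translocation([(3, 4), (6, 0)], home_center=(500.0, 0.0))
        assert straightness(rec) == pytest.approx(0.6)

    def test_zero_length_fix_no_effect(self):
        rec1 = translocation([(3, 4), (6, 0)], home_center=(500.0, 0.0))
        rec2 = translocation([(3, 4), (3, 4), (6, 0)],
                             home_center=(500.0, 0.0), step_min=20)
        assert straightness(rec2) == pytest.approx(straightness(rec1))

    def test_truncated_at_home_buffer_entry(self):
        # wandering after arrival must not dilute the ratio
        arrive = translocation([(25, 0), (46, 0)])
        wander = translocation([(25, 0), (46, 0), (46, 30), (20, 30)])
        assert straightness(wander) == pytest.approx(straightness(arrive))

    def test_never_exceeds_one(self, rng):
        for _ in range(20):
            pts = np.cumsum(rng.normal(0, 5, size=(10, 2)), axis=0)
            rec = translocation([tuple(p) for p in pts],
                                home_center=(300.0, 0.0))
            s = straightness(rec)
            if s is not None:
                assert 0 < s <= 1.0


class TestAngularDeviation:
    def test_aligned_crossing_is_zero(self):
        rec = translocation([(12, 0), (36, 0)])
        dev, interp = angular_deviation(rec)
        assert dev == pytest.approx(0.0)
        assert not interp

    def test_perpendicular_crossing_is_half_pi(self):
        rec = translocation([(0, 12), (36, 0)])
        dev, _ = angular_deviation(rec)
        assert dev == pytest.approx(math.pi / 2)

    def test_stationary_track_undefined(self):
        rec = translocation([(1, 0), (0, 1), (-1, 0)])
        dev, _ = angular_deviation(rec)
        assert dev is None

    def test_band_jump_interpolated_at_center_radius(self):
        # single step from release jumps clean across the [5, 15] annulus
        rec = translocation([(0, 2), (30, 2)], step_min=10)
        dev, interp = angular_deviation(rec)
        assert interp
        # crossing of the r=10 circle on the segment (0,2)->(30,2)
        x = math.sqrt(100 - 4)
        expected = math.atan2(2, x)
        assert dev == pytest.approx(expected, abs=1e-9)

    def test_interp_mode_crosses_center_circle(self):
        rec = translocation([(8, 0), (14, 0), (36, 0)])
        dev, interp = angular_deviation(rec, NavConfig(band_mode="interp"))
        assert dev == pytest.approx(0.0)
        assert interp

    def test_mirror_antisymmetry(self, rng):
        for _ in range(10):
            pts = np.cumsum(rng.normal(2, 3, size=(8, 2)), axis=0)
            rec = translocation([tuple(p) for p in pts])
            mirrored = translocation([(p[0], -p[1]) for p in pts])
            d1, _ = angular_deviation(rec)
            d2, _ = angular_deviation(mirrored)
            if d1 is not None and abs(d1) < math.pi - 1e-9:
                assert d2 == pytest.approx(-d1)


class TestHomingDuration:
    def test_one_night_excluded(self):
        # release noon day 1; fix (20,0) at midnight, fix (50,0) at noon
        # day 2.  The buffered home boundary sits at x=38, so entry
        # interpolates to 07:12 day 2: 19.2 h elapsed minus one 12 h
        # night = 7.2 h
        release_time = datetime(2023, 1, 1, 12, 0)
        rec = translocation([(20, 0), (50, 0)],
                            release_time=release_time, step_min=12 * 60)
        assert homing_duration(rec) == pytest.approx(7.2, abs=1e-9)

    def test_direct_entry_same_day(self):
        # single 2 h step from release to the home center crosses the
        # buffer boundary (x=38) at 76% of the step
        release_time = datetime(2023, 1, 1, 10, 0)
        rec = translocation([(50, 0)], release_time=release_time,
                            step_min=120)
        assert homing_duration(rec) == pytest.approx(
            2.0 * _entry_fraction(), abs=1e-9)

    def test_no_entry_errors(self):
        rec = translocation([(10, 0), (20, 0)])
        with pytest.raises(ValueError, match="inconsistent"):
            homing_duration(rec)

    def test_never_negative(self):
        release_time = datetime(2023, 1, 1, 17, 30)
        rec = translocation([(50, 0)], release_time=release_time,
                            step_min=14 * 60)
        assert homing_duration(rec) >= 0.0


def _entry_fraction():
    # release (0,0), home square center (50,0) with half-width 2 and 10 m
    # buffer: boundary at x=38, so entry at 38/50 of the step
    return 38.0 / 50.0


class TestHomingDurationCalendar:
    def test_hand_calendar_example(self):
        # release noon day 1, track fix already home at noon day 2 with
        # instantaneous last step: elapsed 24 h minus one 12 h night
        release_time = datetime(2023, 1, 1, 12, 0)
        home = square_home((50.0, 0.0))
        fixes = (Fix("a", datetime(2023, 1, 2, 11, 59), 37.9, 0.0),
                 Fix("a", datetime(2023, 1, 2, 12, 0), 50.0, 0.0))
        rec = TranslocationRecord("a", (0.0, 0.0), release_time,
                                  DistanceClass.D50, home,
                                  Trajectory("a", fixes))
        assert homing_duration(rec) == pytest.approx(12.0, abs=0.05)


class TestNormalizeHomeward:
    def test_home_maps_to_plus_y(self):
        rec = translocation([(50, 0)])
        out = normalize_homeward(rec)
        assert out.fixes[0].xy == pytest.approx((0.0, 50.0))

    def test_release_fix_maps_to_origin(self):
        rec = translocation([(0, 0), (10, 10)], home_center=(30.0, 40.0))
        out = normalize_homeward(rec)
        assert out.fixes[0].xy == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_isometry(self, rng):
        pts = rng.uniform(-40, 60, size=(6, 2))
        rec = translocation([tuple(p) for p in pts],
                            home_center=(30.0, 40.0))
        out = normalize_homeward(rec)
        before = rec.track.coords()
        after = out.coords()
        d_before = np.linalg.norm(
            before[:, None, :] - before[None, :, :], axis=-1)
        d_after = np.linalg.norm(
            after[:, None, :] - after[None, :, :], axis=-1)
        assert np.allclose(d_before, d_after)


class TestSummarizeNavigation:
    def test_non_homing_leaves_metrics_undefined(self):
        rec = translocation([(5, 0), (10, 0)])
        s = summarize_navigation(rec)
        assert not s.homing
        assert s.straightness is None and s.homing_duration_h is None
        assert s.explored_area_m2 > 0

    def test_homing_animal_fully_summarized(self):
        rec = translocation([(12, 0), (30, 0), (50, 0)])
        s = summarize_navigation(rec)
        assert s.homing
        assert s.straightness == pytest.approx(1.0)
        assert s.angular_deviation_rad == pytest.approx(0.0)
        assert s.homing_duration_h is not None
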