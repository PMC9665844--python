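"""Space-use metrics against closed forms and brute-force oracles."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from frognav.core import Fix
from frognav.spaceuse import (KDEConfig, daily_travel, home_range_ud,
                              movement_extent_distance,
                              movement_extent_mcp, percent_difference,
                              plugin_bandwidth, summarize_space_use)
from frognav.spaceuse import _dpi_bandwidth_1d

from conftest import traj


def fixes_at(points):
    t0 = datetime(2023, 1, 1, 6)
    return [Fix("a", t0 + timedelta(minutes=30 * i), float(x), float(y))
            for i, (x, y) in enumerate(points)]


def brute_force_hull_area(pts: np.ndarray) -> float:
    """O(n^3) hull: an edge (i, j) is on the hull iff every other point
    lies weakly on one side; the area follows from the shoelace formula
    over the angularly ordered hull vertices."""
    n = len(pts)
    on_hull = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if np.all(cross >= -1e-12) or np.all(cross <= 1e-12):
                on_hull.add(i)
                on_hull.add(j)
    if len(on_hull) < 3:
        return 0.0
    hull = pts[sorted(on_hull)]
    c = hull.mean(axis=0)
    order = np.argsort(np.arctan2(hull[:, 1] - c[1], hull[:, 0] - c[0]))
    hull = hull[order]
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestDailyTravel:
    def test_three_four_five(self):
        assert daily_travel(fixes_at([(0, 0), (3, 4), (3, 4)])) \
            == pytest.approx(5.0)

    def test_single_fix_zero(self):
        assert daily_travel(fixes_at([(7, 7)])) == 0.0

    def test_square_loop_counts_full_perimeter(self):
        pts = [(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)]
        assert daily_travel(fixes_at(pts)) == pytest.approx(40.0)

    def test_rejects_multi_day_fixes(self):
        f = fixes_at([(0, 0)])
        g = [Fix("a", f[0].t + timedelta(days=1), 1, 1)]
        with pytest.raises(ValueError, match="span"):
            daily_travel(f + g)

    def test_travel_at_least_net_displacement(self, rng):
        for _ in range(20):
            pts = rng.uniform(-50, 50, size=(10, 2))
            f = fixes_at(pts)
            net = math.dist(pts[0], pts[-1])
            assert daily_travel(f) >= net - 1e-9


class TestMCP:
    def test_unit_square(self):
        _, area, degen = movement_extent_mcp(
            fixes_at([(0, 0), (1, 0), (1, 1), (0, 1)]))
        assert area == pytest.approx(1.0) and not degen

    def test_interior_point_does_not_change_hull(self):
        _, area, _ = movement_extent_mcp(
            fixes_at([(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)]))
        assert area == pytest.approx(1.0)

    def test_collinear_degenerate(self):
        _, area, degen = movement_extent_mcp(
            fixes_at([(0, 0), (1, 1), (2, 2)]))
        assert area == 0.0 and degen

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            pts = rng.uniform(-100, 100, size=(n, 2))
            _, area, _ = movement_extent_mcp(fixes_at(pts))
            assert area == pytest.approx(brute_force_hull_area(pts),
                                         rel=1e-9, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(-10, 10, size=(12, 2))
        _, area, _ = movement_extent_mcp(fixes_at(pts))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)],
                        [np.sin(th), np.cos(th)]])
        moved = pts @ rot.T + np.array([123.4, -56.7])
        _, area2, _ = movement_extent_mcp(fixes_at(moved))
        assert area2 == pytest.approx(area, rel=1e-9)


class TestExtentDistance:
    def test_hand_distance(self):
        assert movement_extent_distance(fixes_at([(0, 0), (30, 40)])) \
            == pytest.approx(50.0)

    def test_identical_fixes_zero(self):
        assert movement_extent_distance(fixes_at([(5, 5)] * 4)) == 0.0

    def test_single_fix_undefined(self):
        assert movement_extent_distance(fixes_at([(0, 0)])) is None

    def test_matches_pairwise_brute_force(self, rng):
        pts = rng.uniform(-100, 100, size=(100, 2))
        d = movement_extent_distance(fixes_at(pts))
        brute = max(math.dist(p, q) for p in pts for q in pts)
        assert d == pytest.approx(brute, rel=1e-12)

    def test_at_least_any_hull_edge(self, rng):
        pts = rng.uniform(-50, 50, size=(30, 2))
        hull, _, _ = movement_extent_mcp(fixes_at(pts))
        d = movement_extent_distance(fixes_at(pts))
        edges = list(hull.exterior.coords)
        for a, b in zip(edges, edges[1:]):
            assert d >= math.dist(a, b) - 1e-9


class TestPluginBandwidth:
    def test_close_to_normal_reference_on_gaussian(self, rng):
        n = 500
        pts = rng.standard_normal((n, 2))
        hx, hy = plugin_bandwidth(pts)
        h_amise = (4.0 / (3.0 * n)) ** 0.2
        assert hx == pytest.approx(h_amise, rel=0.25)
        assert hy == pytest.approx(h_amise, rel=0.25)

    def test_scale_equivariance(self, rng):
        pts = rng.standard_normal((200, 2))
        hx, hy = plugin_bandwidth(pts)
        hx10, hy10 = plugin_bandwidth(pts * 10.0)
        assert hx10 == pytest.approx(10 * hx, rel=1e-9)
        assert hy10 == pytest.approx(10 * hy, rel=1e-9)

    def test_duplicating_sample_shrinks_bandwidth(self, rng):
        pts = rng.standard_normal((150, 2))
        hx, _ = plugin_bandwidth(pts)
        hx2, _ = plugin_bandwidth(np.vstack([pts, pts]))
        assert hx2 < hx

    def test_zero_variance_axis_errors(self):
        pts = np.column_stack([np.zeros(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="variance"):
            plugin_bandwidth(pts)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="at least 8"):
            plugin_bandwidth(np.random.default_rng(0).normal(size=(5, 2)))

    def test_matches_reference_dpi_selector(self):
        # frozen oracle: R stats::bw.SJ(x, method="dpi") on this exact
        # sample returns 1.6363314990
        rng = np.random.default_rng(42)
        x = np.round(rng.standard_normal(60) * 3
                     + np.concatenate([np.zeros(40), 4 * np.ones(20)]), 6)
        assert _dpi_bandwidth_1d(x) == pytest.approx(1.6363314990, rel=0.02)


class TestHomeRangeUD:
    def test_gaussian_closed_form(self, rng):
        # 95% contour of a standard bivariate normal has area
        # pi * chi2_2(0.95) = pi * 5.991
        pts = rng.standard_normal((2000, 2))
        hr = home_range_ud(pts)
        assert hr.area_m2 == pytest.approx(math.pi * 5.991, rel=0.15)

    def test_area_monotone_in_level(self, rng):
        pts = rng.standard_normal((500, 2))
        a95 = home_range_ud(pts, KDEConfig(ud_level=0.95)).area_m2
        a99 = home_range_ud(pts, KDEConfig(ud_level=0.99)).area_m2
        a50 = home_range_ud(pts, KDEConfig(ud_level=0.50)).area_m2
        assert a50 < a95 < a99

    def test_two_separated_clusters_sum(self, rng):
        # at a common fixed bandwidth the 95% superlevel set of a
        # well-separated balanced mixture splits into two components
        # whose areas add up to the per-cluster areas
        a = rng.standard_normal((800, 2))
        b = rng.standard_normal((800, 2)) + np.array([200.0, 0.0])
        h = (0.35, 0.35)
        cfg = KDEConfig(grid_cells=256, bandwidth=h)
        area_a = home_range_ud(a, cfg).area_m2
        area_b = home_range_ud(b, cfg).area_m2
        both = home_range_ud(np.vstack([a, b]),
                             KDEConfig(grid_cells=1024, bandwidth=h))
        assert both.area_m2 == pytest.approx(area_a + area_b, rel=0.15)
        assert len(both.polygons) >= 2

    def test_contour_polygons_cover_threshold_mass(self, rng):
        pts = rng.standard_normal((300, 2))
        hr = home_range_ud(pts)
        assert hr.polygons
        total = sum(p.area for p in hr.polygons)
        assert total == pytest.approx(hr.area_m2, rel=0.1)


class TestPercentDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (2.53, 1.00, 153.0), (1.0, 1.0, 0.0), (0.44, 1.00, -56.0)])
    def test_definition(self, a, b, expected):
        assert percent_difference(a, b) == pytest.approx(expected)

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestSummarizeSpaceUse:
    def test_short_tracking_gets_travel_only(self):
        tr = traj([(0, 0), (3, 4)], step_min=60)
        s = summarize_space_use(tr)
        assert s.daily_travel_mean_m == pytest.approx(5.0)
        assert s.extent_area_m2 is None and s.home_range_m2 is None

    def test_long_tracking_gets_all_metrics(self, rng):
        t0 = datetime(2023, 1, 1, 8)
        fixes = []
        pts = rng.normal(0, 5, size=(28, 2))
        for d in range(7):
            for k in range(4):
                i = d * 4 + k
                fixes.append(Fix("a", t0 + timedelta(days=d, hours=2 * k),
                                 *pts[i]))
        from frognav.core import Trajectory
        s = summarize_space_use(Trajectory("a", tuple(fixes)))
        assert s.days_tracked == 7
        assert s.extent_area_m2 > 0
        assert s.extent_distance_m > 0
        assert s.home_range_m2 > 0
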