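import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon as ShapelyPolygon

from alveo4d import alveolus as alv
from alveo4d import simulate as sim


def _circle(n, r, center=(0.0, 0.0), jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ang = (np.arange(n) + rng.uniform(0, 1, n) * jitter) * 2 * math.pi / n
    return np.stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)], axis=1)


class TestPartition:
    def test_distinct_times_counted(self):
        cloud = pd.DataFrame({"t": [0, 1, 1, 2], "x": 0.0, "y": 0.0, "z": 0.0})
        assert len(alv.partition_by_time(cloud)) == 3

    def test_single_time_single_snapshot(self):
        cloud = pd.DataFrame({"t": [5.0] * 4, "x": 0.0, "y": 0.0, "z": 0.0})
        parts = alv.partition_by_time(cloud)
        assert len(parts) == 1 and parts[0][0] == 5.0

    def test_union_of_snapshots_is_cloud(self):
        cloud = sim.alveolus_cloud(n_frames=20, seed=1)
        parts = alv.partition_by_time(cloud)
        assert len(parts) == 20
        assert sum(len(df) for _t, df in parts) == len(cloud)

    def test_empty_or_non_finite_rejected(self):
        with pytest.raises(ValueError):
            alv.partition_by_time(pd.DataFrame(columns=["t", "x", "y", "z"]))
        bad = pd.DataFrame({"t": [0.0], "x": [np.nan], "y": [0.0], "z": [0.0]})
        with pytest.raises(ValueError):
            alv.partition_by_time(bad)


class TestSlice:
    def test_inclusive_tolerance_boundary(self):
        snap = pd.DataFrame({"t": 0.0, "x": [1.0, 2.0], "y": 0.0, "z": [10.25, 10.75]})
        assert len(alv.planar_slice(snap, 10.0, 0.75)) == 2  # both within, inclusive
        assert len(alv.planar_slice(snap, 10.0, 0.25)) == 1  # z=10.25 kept, 10.75 dropped
        assert len(alv.planar_slice(snap, 10.0, 0.2)) == 0

    def test_zero_tolerance_keeps_exact_matches(self):
        snap = pd.DataFrame({"t": 0.0, "x": [1.0, 2.0], "y": 0.0, "z": [10.0, 11.0]})
        assert len(alv.planar_slice(snap, 10.0, 0.0)) == 1

    def test_equatorial_slice_of_shell_is_annulus(self):
        cloud = sim.alveolus_cloud(n_frames=1, r0=10.0, seed=2)
        pts = alv.planar_slice(cloud[cloud.t == 0], 40.0, 0.5)
        radii = np.linalg.norm(pts - [40.0, 40.0], axis=1)
        assert len(pts) > 50
        assert np.all(np.abs(radii - 10.0) < 1.0)

    def test_negative_tolerance_rejected(self):
        snap = pd.DataFrame({"t": 0.0, "x": [1.0], "y": [0.0], "z": [0.0]})
        with pytest.raises(ValueError):
            alv.planar_slice(snap, 0.0, -1.0)


class TestClosedSets:
    def test_outer_of_concentric_circles_selected_first(self):
        pts = np.vstack([_circle(80, 10.0), _circle(120, 30.0)])
        loops = alv.closed_sets(pts, eps=2.5)
        assert len(loops) == 2
        r_first = np.linalg.norm(loops[0], axis=1).mean()
        assert r_first == pytest.approx(30.0, abs=0.5)

    def test_open_arc_yields_no_loop(self):
        ang = np.linspace(0, math.pi, 60)  # half circle
        pts = np.stack([10 * np.cos(ang), 10 * np.sin(ang)], axis=1)
        assert alv.closed_sets(pts, eps=1.0) == []

    def test_single_square_sampling_found(self):
        side = np.linspace(0, 10, 26)[:-1]
        pts = np.vstack([
            np.stack([side, np.zeros_like(side)], 1),
            np.stack([np.full_like(side, 10.0), side], 1),
            np.stack([side[::-1], np.full_like(side, 10.0)], 1),
            np.stack([np.zeros_like(side), side[::-1]], 1),
        ])
        loops = alv.closed_sets(pts, eps=1.0)
        assert len(loops) == 1
        assert len(loops[0]) == len(pts)


class TestFitPolygon:
    def test_scrambled_square_corners_ordered(self):
        pts = np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        poly = alv.fit_polygon(pts)
        a, p, r = alv.polygon_measures(poly)
        assert a == pytest.approx(1.0)
        assert p == pytest.approx(4.0)

    def test_circle_sampling_simple_polygon(self):
        poly = alv.fit_polygon(_circle(64, 10.0))
        assert ShapelyPolygon(poly).is_valid
        assert len(poly) == 64

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            alv.fit_polygon(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))

    def test_orientation_counterclockwise(self):
        poly = alv.fit_polygon(_circle(32, 5.0)[::-1])
        x, y = poly[:, 0], poly[:, 1]
        signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert signed > 0


class TestMeasures:
    def test_unit_square_closed_form(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        assert alv.polygon_measures(square) == pytest.approx((1.0, 4.0, 0.25))

    def test_360gon_ratio_near_half_radius(self):
        poly = np.stack([10 * np.cos(np.linspace(0, 2 * math.pi, 361)[:-1]),
                         10 * np.sin(np.linspace(0, 2 * math.pi, 361)[:-1])], axis=1)
        _a, _p, r = alv.polygon_measures(poly)
        assert abs(r - 5.0) / 5.0 < 1e-3
        # closed form A/P = (r/2) cos(pi/n) for the inscribed regular n-gon
        assert r == pytest.approx(5.0 * math.cos(math.pi / 360), rel=1e-9)

    def test_scaling_law(self):
        poly = _circle(32, 4.0)
        a1, p1, r1 = alv.polygon_measures(poly)
        a2, p2, r2 = alv.polygon_measures(2 * poly)
        assert a2 == pytest.approx(4 * a1)
        assert p2 == pytest.approx(2 * p1)
        assert r2 == pytest.approx(2 * r1)

    def test_convex_loop_ratio_bounded_by_half_circumradius(self):
        for n in (8, 32, 128):
            poly = _circle(n, 7.0)
            _a, _p, r = alv.polygon_measures(poly)
            assert r <= 7.0 / 2 + 1e-9

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(5, 40), st.integers(0, 10_000))
    def test_shoelace_matches_shapely_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        # random star-shaped (hence simple) polygon
        ang = np.sort(rng.uniform(0, 2 * math.pi, n))
        rad = rng.uniform(2.0, 10.0, n)
        poly = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        a, p, _r = alv.polygon_measures(poly)
        shp = ShapelyPolygon(poly)
        assert a == pytest.approx(shp.area, rel=1e-9)
        assert p == pytest.approx(shp.length, rel=1e-9)


class TestExpansionSeries:
    def test_static_circle_constant_series(self):
        frames = []
        base = _circle(100, 10.0, center=(40, 40))
        for t in range(5):
            frames.append(pd.DataFrame({"t": float(t), "x": base[:, 0],
                                        "y": base[:, 1], "z": 40.0}))
        series = alv.expansion_series(pd.concat(frames), 40.0)
        assert series.A.nunique() == 1
        assert series.P.nunique() == 1

    def test_expanding_alveolus_area_ratio_near_four(self):
        cloud = sim.alveolus_cloud(r0=10.0, r1=20.0, seed=3)
        series = alv.expansion_series(cloud, 40.0).dropna()
        assert series.A.is_monotonic_increasing
        ratio = series.A.iloc[-1] / series.A.iloc[0]
        assert abs(ratio - 4.0) / 4.0 < 0.10

    def test_wnt_perturbed_flat_series(self):
        cloud = sim.alveolus_cloud(mode="wnt_inhibited", seed=4)
        series = alv.expansion_series(cloud, 40.0).dropna()
        rel_slope = np.polyfit(series.t, series.A, 1)[0] / series.A.mean()
        assert abs(rel_slope) < 0.01  # per hour, indistinguishable from noise
        rel_slope_p = np.polyfit(series.t, series.P, 1)[0] / series.P.mean()
        assert abs(rel_slope_p) < 0.01

    def test_permutation_invariance_of_input_order(self):
        cloud = sim.alveolus_cloud(seed=5, n_frames=4)
        shuffled = cloud.sample(frac=1.0, random_state=7).reset_index(drop=True)
        s1 = alv.expansion_series(cloud, 40.0)
        s2 = alv.expansion_series(shuffled, 40.0)
        pd.testing.assert_frame_equal(s1, s2)
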