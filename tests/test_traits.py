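"""Plant height, convex hull, rotating calipers, crown width, R²/RMSE."""

import numpy as np
import pytest

import railphen as rp

FLAT = rp.PlaneModel(0, 0, 1, 0)    # calibrated ground at z = 0


def brute_force_diameter(pts2d):
    d2 = ((pts2d[:, None, :] - pts2d[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


class TestPlantHeight:
    def test_direct_formula(self):
        pts = np.array([[0, 0, 0.1], [0.1, 0, 0.50]])
        res = rp.plant_height(pts, FLAT, hp=0.10)
        assert np.isclose(res.height, 0.40, atol=1e-12)
        assert res.z_max == 0.50 and res.z_min == 0.0 and res.valid

    def test_single_point_no_pot(self):
        res = rp.plant_height(np.array([[1, 2, 0.25]]), FLAT, hp=0.0)
        assert np.isclose(res.height, 0.25)

    def test_nonpositive_height_flagged_invalid(self):
        res = rp.plant_height(np.array([[0, 0, 0.05]]), FLAT, hp=0.10)
        assert res.height < 0 and not res.valid

    def test_invariant_under_xy_translation(self, rng):
        pts = rng.uniform(0, 0.3, (50, 3))
        a = rp.plant_height(pts, FLAT, 0.1).height
        b = rp.plant_height(pts + [5.0, -3.0, 0.0], FLAT, 0.1).height
        assert np.isclose(a, b, atol=1e-12)

    def test_zmin_from_plane_at_centroid(self):
        # tilted ground: z = 0.1 x  ->  normal (-0.1,0,1)/n, D=0
        plane = rp.PlaneModel(-0.1, 0, 1, 0)
        pts = np.array([[2.0, 0, 0.9], [2.0, 0, 0.6]])
        res = rp.plant_height(pts, plane, hp=0.0)
        assert np.isclose(res.z_min, 0.2, atol=1e-12)
        assert np.isclose(res.height, 0.7, atol=1e-12)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            rp.plant_height(np.empty((0, 3)), FLAT, 0.1)


class TestProjectXY:
    def test_drops_z(self):
        assert np.array_equal(rp.project_xy(np.array([[1.0, 2.0, 3.0]])), [[1, 2]])

    def test_count_and_duplicates_preserved(self, rng):
        pts = np.repeat(rng.normal(size=(5, 3)), 2, axis=0)
        assert len(rp.project_xy(pts)) == 10

    def test_idempotent(self, rng):
        pts = rng.normal(size=(20, 3))
        once = rp.project_xy(pts)
        twice = rp.project_xy(np.column_stack([once, np.zeros(20)]))
        assert np.array_equal(once, twice)


class TestConvexHull:
    def test_square_with_interior_points(self, rng):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        pts = np.vstack([corners, rng.uniform(0.01, 0.99, (100, 2))])
        hull = rp.convex_hull(pts)
        assert len(hull) == 4
        assert {tuple(v) for v in hull.vertices} == {tuple(c) for c in corners}

    def test_ccw_orientation(self):
        hull = rp.convex_hull(np.array([[0, 0], [2, 0], [1, 2]], dtype=float))
        v = hull.vertices
        area2 = 0.0
        for i in range(len(v)):
            j = (i + 1) % len(v)
            area2 += v[i, 0] * v[j, 1] - v[j, 0] * v[i, 1]
        assert area2 > 0

    def test_collinear_input_two_extremes(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        hull = rp.convex_hull(pts)
        assert len(hull) == 2
        assert {tuple(v) for v in hull.vertices} == {(0.0, 0.0), (4.0, 4.0)}

    def test_matches_scipy_qhull(self, rng):
        from scipy.spatial import ConvexHull as SciHull
        for _ in range(25):
            pts = rng.normal(size=(int(rng.integers(5, 80)), 2))
            mine = {tuple(v) for v in rp.convex_hull(pts).vertices}
            ref = {tuple(pts[i]) for i in SciHull(pts).vertices}
            assert mine == ref


class TestCalipersDiameter:
    def test_unit_square_diagonal(self):
        hull = rp.convex_hull(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))
        L, pair = rp.calipers_diameter(hull)
        assert np.isclose(L, np.sqrt(2), atol=1e-12)
        assert np.allclose(np.abs(pair[0] - pair[1]), [1, 1])

    def test_two_vertex_hull(self):
        L, _ = rp.calipers_diameter(rp.Hull2D(np.array([[0, 0], [2, 0]])))
        assert L == 2.0

    def test_single_vertex_zero(self):
        L, _ = rp.calipers_diameter(rp.Hull2D(np.array([[3, 4]])))
        assert L == 0.0

    def test_regular_hexagon(self):
        ang = np.arange(6) * np.pi / 3
        hull = rp.convex_hull(np.column_stack([np.cos(ang), np.sin(ang)]))
        L, _ = rp.calipers_diameter(hull)
        assert np.isclose(L, 2.0, atol=1e-12)

    def test_equals_brute_force_exactly(self, rng):
        for _ in range(60):
            pts = rng.normal(size=(int(rng.integers(3, 200)), 2))
            L, _ = rp.calipers_diameter(rp.convex_hull(pts))
            assert L == brute_force_diameter(pts)

    def test_rotation_invariance_about_z(self, rng):
        pts = rng.normal(size=(100, 3))
        L0 = rp.max_crown_width(pts + [0, 0, 10], FLAT, 0.0, exclude_pot=False).width
        for theta in (0.3, 1.2, 2.9):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            Lr = rp.max_crown_width(pts @ R.T + [0, 0, 10], FLAT, 0.0,
                                    exclude_pot=False).width
            assert np.isclose(Lr, L0, atol=1e-9)

    def test_scales_linearly_in_xy(self, rng):
        pts = rng.normal(size=(50, 3)) + [0, 0, 10]
        L0 = rp.max_crown_width(pts, FLAT, 0.0, exclude_pot=False).width
        scaled = pts * [2.5, 2.5, 1.0]
        L1 = rp.max_crown_width(scaled, FLAT, 0.0, exclude_pot=False).width
        assert np.isclose(L1, 2.5 * L0, atol=1e-9)


class TestMaxCrownWidth:
    def test_flat_disk_diameter(self):
        ang = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        disk = np.column_stack([0.15 * np.cos(ang), 0.15 * np.sin(ang),
                                np.full(360, 0.5)])
        res = rp.max_crown_width(disk, FLAT, hp=0.1)
        assert np.isclose(res.width, 0.30, atol=1e-9)

    def test_wide_pot_excluded(self):
        ang = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        canopy = np.column_stack([0.10 * np.cos(ang), 0.10 * np.sin(ang),
                                  np.full(90, 0.5)])
        pot = np.column_stack([0.30 * np.cos(ang), 0.30 * np.sin(ang),
                               np.full(90, 0.05)])
        pts = np.vstack([canopy, pot])
        assert np.isclose(rp.max_crown_width(pts, FLAT, hp=0.1).width, 0.20, atol=1e-9)
        # with exclusion off the wide pot defines the width
        assert np.isclose(rp.max_crown_width(pts, FLAT, hp=0.1,
                                             exclude_pot=False).width, 0.60, atol=1e-9)

    def test_single_canopy_point_zero_width(self):
        res = rp.max_crown_width(np.array([[0, 0, 0.5]]), FLAT, hp=0.1)
        assert res.width == 0.0 and res.valid

    def test_nothing_above_rim_invalid(self):
        res = rp.max_crown_width(np.array([[0, 0, 0.05]]), FLAT, hp=0.1)
        assert not res.valid and np.isnan(res.width)


class TestEvaluate:
    def test_perfect_agreement(self):
        rep = rp.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isclose(rep.r_squared, 1.0) and rep.rmse == 0.0
        assert np.isclose(rep.slope, 1.0) and np.isclose(rep.intercept, 0.0)

    def test_hand_computed_rmse(self):
        rep = rp.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert np.isclose(rep.rmse, np.sqrt(1.0 / 3.0), atol=1e-12)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rp.evaluate([1.0, 2.0], [3.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rp.evaluate([1.0], [1.0, 2.0])

    def test_r_squared_in_unit_interval(self, rng):
        for _ in range(20):
            meas = rng.normal(size=10)
            est = meas + rng.normal(0, 2.0, 10)
            rep = rp.evaluate(est, meas)
            assert 0.0 <= rep.r_squared <= 1.0
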