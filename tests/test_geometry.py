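"""Geometry core: resampling, Menger curvature, curvature index, Cobb and
embryo angles, rose binning — checked against analytic and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scoliomorph as sm
from scoliomorph.geometry import cobb_angle_perpendicular, smooth_midline


def circle_polyline(radius, n, sweep=2 * math.pi, closed=False):
    t = np.linspace(0.0, sweep, n)
    xy = np.column_stack([radius * np.cos(t), radius * np.sin(t)])
    if closed:
        xy[-1] = xy[0]
    return sm.Polyline.from_xy(xy)


def brute_force_circumradius(a, b, c):
    """Circumcentre via the linear system |p-a|^2 = |p-b|^2 = |p-c|^2."""
    a, b, c = map(np.asarray, (a, b, c))
    A = 2.0 * np.array([b - a, c - a])
    rhs = np.array([b @ b - a @ a, c @ c - a @ a])
    det = np.linalg.det(A)
    if abs(det) < 1e-14:
        return np.inf
    centre = np.linalg.solve(A, rhs)
    return np.linalg.norm(centre - a)


class TestResample:
    def test_straight_segment_uniform_spacing(self):
        pl = sm.Polyline.from_xy(np.array([[0.0, 0.0], [10.0, 0.0]]))
        m = sm.resample_equidistant(pl, 5)
        assert [p.x for p in m.points] == pytest.approx([0, 2.5, 5, 7.5, 10])
        assert m.spacing == pytest.approx(2.5)

    def test_v_shape_midpoint_lands_on_vertex(self):
        pl = sm.Polyline.from_xy(np.array([[0, 0], [3, 4], [6, 0]], float))
        m = sm.resample_equidistant(pl, 3)
        assert (m.points[1].x, m.points[1].y) == pytest.approx((3.0, 4.0))

    def test_quarter_circle_equal_chords_and_length(self):
        pl = circle_polyline(10.0, 1000, sweep=math.pi / 2)
        m = sm.resample_equidistant(pl, 50)
        chords = np.linalg.norm(np.diff(m.xy, axis=0), axis=1)
        assert np.ptp(chords) / chords.mean() < 1e-6
        # oracle: dense numerical arc length of the quarter circle
        assert m.total_length == pytest.approx(5 * math.pi, rel=1e-4)

    def test_endpoints_preserved(self):
        pl = circle_polyline(3.0, 200, sweep=1.0)
        m = sm.resample_equidistant(pl, 7)
        assert m.xy[0] == pytest.approx(pl.xy[0])
        assert m.xy[-1] == pytest.approx(pl.xy[-1])

    def test_parameter_errors(self):
        pl = sm.Polyline.from_xy(np.array([[0.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            sm.resample_equidistant(pl, 2)
        with pytest.raises(ValueError):
            sm.Polyline.from_xy(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestMengerCurvature:
    def test_collinear_points_have_zero_curvature(self):
        assert sm.menger_curvature((0, 0), (1, 0), (2, 0)) == 0.0

    def test_cocircular_points_recover_radius(self):
        ang = np.radians([0.0, 10.0, 20.0])
        pts = [(10 * math.cos(a), 10 * math.sin(a)) for a in ang]
        assert abs(sm.menger_curvature(*pts)) == pytest.approx(0.1, rel=1e-12)

    def test_isoceles_triangle_unit_circumcircle(self):
        # circumcircle of (0,0),(1,1),(2,0) has centre (1,0), radius 1;
        # the turn is clockwise, hence negative under ccw-positive convention
        k = sm.menger_curvature((0, 0), (1, 1), (2, 0))
        assert k == pytest.approx(-1.0, rel=1e-12)
        assert 1.0 / abs(k) == pytest.approx(
            brute_force_circumradius((0, 0), (1, 1), (2, 0)), rel=1e-12
        )

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            sm.menger_curvature((0, 0), (0, 0), (1, 0))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(-20, 20), st.integers(-20, 20)), min_size=3, max_size=6))
    def test_oracle_equivalence_brute_force_circumcentre(self, pts):
        pts = [np.array(p, float) for p in pts]
        for a, b, c in zip(pts, pts[1:], pts[2:]):
            if min(np.linalg.norm(b - a), np.linalg.norm(c - b), np.linalg.norm(a - c)) == 0:
                continue
            r = brute_force_circumradius(a, b, c)
            k = sm.menger_curvature(a, b, c)
            if np.isinf(r):
                assert k == pytest.approx(0.0, abs=1e-9)
            else:
                assert abs(k) == pytest.approx(1.0 / r, rel=1e-9)


class TestCurvatureProfile:
    def test_full_circle_constant_curvature(self):
        # 793 = 99*8 + 1 source vertices: the 100 resample targets land on
        # every 8th vertex exactly, so the samples are cocircular
        pl = circle_polyline(5.0, 793, closed=True)
        prof = sm.curvature_profile(sm.resample_equidistant(pl, 100))
        assert np.allclose(np.abs(prof.curvatures), 0.2, rtol=1e-9)
        assert len(set(np.sign(prof.curvatures))) == 1

    def test_straight_line_all_zero(self):
        pl = sm.Polyline.from_xy(np.column_stack([np.linspace(0, 9, 10), np.zeros(10)]))
        prof = sm.curvature_profile(sm.resample_equidistant(pl, 20))
        assert np.allclose(prof.curvatures, 0.0)

    def test_open_profile_excludes_endpoints(self):
        pl = circle_polyline(5.0, 500, sweep=1.0)
        prof = sm.curvature_profile(sm.resample_equidistant(pl, 40))
        assert prof.curvatures.size == 38

    def test_sine_crest_curvature_matches_analytic(self):
        A, lam, L = 2.0, 20.0, 40.0
        w = 2 * math.pi / lam
        x = np.linspace(0, L, 4000)
        pl = sm.Polyline.from_xy(np.column_stack([x, A * np.sin(w * x)]))
        prof = sm.curvature_profile(sm.resample_equidistant(pl, 400))
        # oracle: kappa = |y''| / (1 + y'^2)^1.5, maximal at the crests
        assert np.abs(prof.curvatures).max() == pytest.approx(A * w**2, rel=0.01)


class TestCurvatureIndex:
    def test_straight_line_zero_index(self):
        pl = sm.Polyline.from_xy(np.column_stack([np.arange(10.0), np.zeros(10)]))
        res = sm.curvature_index(sm.curvature_profile(sm.resample_equidistant(pl, 50)))
        assert res.raw_sum == 0.0 and res.arc_integral == 0.0

    def test_closed_circle_total_turning_two_pi(self):
        pl = circle_polyline(7.0, 4001, closed=True)
        res = sm.curvature_index(sm.curvature_profile(sm.resample_equidistant(pl, 721)))
        assert res.arc_integral == pytest.approx(2 * math.pi, abs=1e-3)

    def test_open_circle_raw_sum_n_minus_2_over_r(self):
        pl = circle_polyline(10.0, 4000, sweep=math.pi / 2)
        res = sm.curvature_index(sm.curvature_profile(sm.resample_equidistant(pl, 50)))
        assert res.raw_sum == pytest.approx(48 / 10.0, rel=1e-6)

    def test_closed_convex_error_decreases_monotonically(self):
        # circle polygons with exactly n vertices: discretisation is the only
        # error source, so |arc_integral - 2*pi| must shrink as n grows
        errs = []
        for n in (36, 72, 144, 288):
            pl = circle_polyline(5.0, n, closed=True)
            m = sm.resample_equidistant(pl, n)
            res = sm.curvature_index(sm.curvature_profile(m))
            errs.append(abs(res.arc_integral - 2 * math.pi))
        assert errs == sorted(errs, reverse=True)

    def test_arc_integral_equals_raw_sum_times_spacing(self):
        pl = circle_polyline(4.0, 500, sweep=2.0)
        prof = sm.curvature_profile(sm.resample_equidistant(pl, 60))
        res = sm.curvature_index(prof)
        assert res.arc_integral == pytest.approx(res.raw_sum * prof.spacing, rel=1e-12)

    def test_empty_profile_rejected(self):
        prof = sm.CurvatureProfile(curvatures=np.array([]), spacing=1.0)
        with pytest.raises(ValueError):
            sm.curvature_index(prof)


class TestCombinedIndex:
    def _res(self, raw, n=50, unit="px"):
        return sm.CurvatureIndexResult(
            raw_sum=raw, arc_integral=raw * 0.5, view=sm.View.LATERAL, n_points=n, unit=unit
        )

    def test_additivity(self):
        assert sm.combined_curvature_index(self._res(0.4), self._res(0.3)).raw_sum == pytest.approx(0.7)

    def test_zero_view_is_identity(self):
        total = sm.combined_curvature_index(self._res(0.4), self._res(0.0))
        assert total.raw_sum == pytest.approx(0.4)

    def test_two_identical_views_double_the_index(self):
        x = np.linspace(0, 40, 2000)
        pl = sm.Polyline.from_xy(np.column_stack([x, 2 * np.sin(2 * np.pi * x / 20)]))
        single = sm.curvature_index(sm.curvature_profile(sm.resample_equidistant(pl, 100)))
        total = sm.combined_curvature_index(single, single)
        assert total.raw_sum == pytest.approx(2 * single.raw_sum, rel=1e-12)
        assert total.arc_integral == pytest.approx(2 * single.arc_integral, rel=1e-12)

    def test_mismatched_configuration_refused(self):
        with pytest.raises(ValueError):
            sm.combined_curvature_index(self._res(0.4, n=50), self._res(0.3, n=100))
        with pytest.raises(ValueError):
            sm.combined_curvature_index(self._res(0.4, unit="mm"), self._res(0.3, unit="px"))


class TestCobbAngle:
    def _line(self, dx, dy, origin=(0.0, 0.0)):
        return sm.LandmarkLine(
            sm.Point2D(*origin), sm.Point2D(origin[0] + dx, origin[1] + dy)
        )

    def test_45_degrees(self):
        assert sm.cobb_angle(self._line(1, 0), self._line(1, 1)) == pytest.approx(45.0)

    def test_parallel_lines_zero(self):
        assert sm.cobb_angle(self._line(2, 1), self._line(4, 2, origin=(5, 5))) == pytest.approx(0.0, abs=1e-5)

    def test_perpendicular_lines_90(self):
        assert sm.cobb_angle(self._line(2, 1), self._line(-1, 2)) == pytest.approx(90.0)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            sm.LandmarkLine(sm.Point2D(1, 1), sm.Point2D(1, 1))

    def test_dual_formulation_equality_on_random_pairs(self):
        # clinical construction: angle between perpendiculars == angle between lines
        rng = np.random.default_rng(11)
        for _ in range(1000):
            a = self._line(*rng.uniform(-5, 5, 2))
            b = self._line(*rng.uniform(-5, 5, 2), origin=tuple(rng.uniform(-9, 9, 2)))
            assert sm.cobb_angle(a, b) == cobb_angle_perpendicular(a, b)

    def test_total_cobb_sums_and_empty_is_zero(self):
        assert sm.total_cobb([]) == 0.0
        mk = lambda ang: sm.CobbMeasurement(  # noqa: E731
            self._line(1, 0), self._line(1, math.tan(math.radians(ang))), angle=ang
        )
        assert sm.total_cobb([mk(30.0), mk(15.5)]) == pytest.approx(45.5)


class TestEmbryoDeflection:
    def _lm(self, tail):
        return sm.EmbryoLandmarks(
            sm.Point2D(0, 0), sm.Point2D(1, 0), sm.Point2D(*tail)
        )

    def test_straight_body_zero(self):
        assert sm.embryo_deflection_angle(self._lm((2, 0))) == pytest.approx(0.0)

    def test_tail_up_right_angle(self):
        assert sm.embryo_deflection_angle(self._lm((1, 1))) == pytest.approx(90.0)

    def test_tail_down_315(self):
        assert sm.embryo_deflection_angle(self._lm((2, -1))) == pytest.approx(315.0)

    def test_rotation_oracle(self):
        # brute force: rotate v into u's frame and read off atan2
        rng = np.random.default_rng(5)
        for _ in range(200):
            eye, yolk, tail = rng.uniform(-3, 3, (3, 2))
            if np.allclose(yolk, eye) or np.allclose(tail, yolk):
                continue
            u, v = yolk - eye, tail - yolk
            phi = math.atan2(u[1], u[0])
            rot = np.array([[math.cos(-phi), -math.sin(-phi)], [math.sin(-phi), math.cos(-phi)]])
            expected = math.degrees(math.atan2(*(rot @ v)[::-1])) % 360
            lm = sm.EmbryoLandmarks(sm.Point2D(*eye), sm.Point2D(*yolk), sm.Point2D(*tail))
            assert sm.embryo_deflection_angle(lm) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_landmarks_rejected(self):
        with pytest.raises(ValueError):
            sm.EmbryoLandmarks(sm.Point2D(0, 0), sm.Point2D(0, 0), sm.Point2D(1, 1))


class TestRoseBin:
    def test_half_open_bin_edges(self):
        rose = sm.rose_bin([0.0, 29.999])
        assert rose.counts[0] == 2

    def test_left_closed_boundary(self):
        assert sm.rose_bin([30.0]).counts[1] == 1

    def test_uniform_angles_within_binomial_bound(self):
        rng = np.random.default_rng(7)
        angles = rng.uniform(0, 360, 1000)
        rose = sm.rose_bin(angles)
        bound = 4 * math.sqrt(1000 / 12)
        assert np.all(np.abs(rose.counts - 1000 / 12) < bound)
        # oracle: direct enumeration
        expected = [np.sum((angles >= 30 * k) & (angles < 30 * (k + 1))) for k in range(12)]
        assert rose.counts.tolist() == expected

    def test_out_of_range_angles_normalised(self):
        rose = sm.rose_bin([-30.0, 390.0])
        assert rose.counts[11] == 1 and rose.counts[1] == 1

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 359.999), max_size=50))
    def test_counts_conserved(self, angles):
        assert sm.rose_bin(angles).total == len(angles)
        assert sm.rose_bin(angles).counts.sum() == len(angles)


class TestInvariances:
    def _random_midline(self, rng):
        x = np.linspace(0, 40, 300)
        y = rng.uniform(0.5, 3) * np.sin(2 * np.pi * x / rng.uniform(10, 30) + rng.uniform(0, 6))
        return np.column_stack([x, y])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            xy = self._random_midline(rng)
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            moved = xy @ R.T + rng.uniform(-100, 100, 2)
            r1 = sm.curvature_index(sm.curvature_profile(sm.resample_equidistant(sm.Polyline.from_xy(xy), 50)))
            r2 = sm.curvature_index(sm.curvature_profile(sm.resample_equidistant(sm.Polyline.from_xy(moved), 50)))
            assert r2.raw_sum == pytest.approx(r1.raw_sum, rel=1e-9)
            assert r2.arc_integral == pytest.approx(r1.arc_integral, rel=1e-9)

    def test_cobb_rigid_motion_invariance(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            p = rng.uniform(-5, 5, (4, 2))
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            q = p @ R.T + rng.uniform(-20, 20, 2)
            mk = lambda a, b: sm.LandmarkLine(sm.Point2D(*a), sm.Point2D(*b))  # noqa: E731
            assert sm.cobb_angle(mk(p[0], p[1]), mk(p[2], p[3])) == pytest.approx(
                sm.cobb_angle(mk(q[0], q[1]), mk(q[2], q[3])), rel=1e-9
            )

    @pytest.mark.parametrize("s", [0.5, 2.0, 10.0])
    def test_scaling_law(self, s):
        rng = np.random.default_rng(23)
        xy = self._random_midline(rng)
        base_prof = sm.curvature_profile(sm.resample_equidistant(sm.Polyline.from_xy(xy), 50))
        scaled_prof = sm.curvature_profile(sm.resample_equidistant(sm.Polyline.from_xy(xy * s), 50))
        assert np.allclose(scaled_prof.curvatures, base_prof.curvatures / s, rtol=1e-9)
        b, c = sm.curvature_index(base_prof), sm.curvature_index(scaled_prof)
        assert c.raw_sum == pytest.approx(b.raw_sum / s, rel=1e-9)
        assert c.arc_integral == pytest.approx(b.arc_integral, rel=1e-9)

    def test_index_strictly_monotone_in_amplitude(self):
        vals = []
        for A in (0.0, 0.5, 1.0, 2.0, 4.0):
            x = np.linspace(0, 40, 2000)
            pl = sm.Polyline.from_xy(np.column_stack([x, A * np.sin(2 * np.pi * x / 20)]))
            vals.append(
                sm.curvature_index(sm.curvature_profile(sm.resample_equidistant(pl, 100))).raw_sum
            )
        assert all(a < b for a, b in zip(vals, vals[1:]))


def test_smoothing_window_reduces_jitter_curvature():
    rng = np.random.default_rng(9)
    x = np.linspace(0, 400, 3000)
    xy = np.column_stack([x, 20 * np.sin(2 * np.pi * x / 200)]) + rng.normal(0, 0.4, (3000, 2))
    m = sm.resample_equidistant(sm.Polyline.from_xy(xy), 50)
    raw = sm.curvature_index(sm.curvature_profile(m)).raw_sum
    smoothed = sm.curvature_index(sm.curvature_profile(m, smooth_window=5)).raw_sum
    true = 0.5012  # quadrature value for this noiseless sine at n_points=50
    assert abs(smoothed - true) < abs(raw - true)
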