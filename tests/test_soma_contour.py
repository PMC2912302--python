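import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somabda.nucleus import c90
from somabda.phantoms import PhantomSpec, add_extensions, half_ellipsoid, v_sum
from somabda.pipeline import bda_report_norot
from somabda.pipeline import PipelineConfig
from somabda.regrid import RotatedGrid, rotate_scan
from somabda.soma_contour import (
    LineProfile,
    fit_best,
    fit_one_point,
    fit_three_points,
    fit_two_points,
    line_boundary,
    line_profile,
    soma_region,
)

# noiseless phantoms: no plane correction, no dish cut
PHANTOM_CFG = PipelineConfig(min_height=0.0, plane_correction=False)


def profile(zs, dx=1.0, opposite_z=0.0, direction="front"):
    zs = np.asarray(zs, float)
    return LineProfile(
        yprime=0.0, direction=direction, xs=np.arange(zs.size) * dx, zs=zs,
        dx=dx, opposite_z=opposite_z,
    )


def make_rgrid(rows):
    """RotatedGrid from a dict {yprime: row over xlevels}."""
    ys = sorted(rows)
    z = np.array([rows[y] for y in ys], float)
    nx = z.shape[1]
    xlevels = np.arange(nx) - nx // 2.0
    return RotatedGrid(xlevels=xlevels, ylevels=np.array(ys, float), z=z)


class TestLineProfile:
    def test_descending_run(self):
        p = profile([5, 4, 3, 2, 1, 0, 0])
        assert p.run_len == 5
        assert np.array_equal(p.t4, [5, 4, 3, 2])
        assert p.N == 4

    def test_gap_stops_run_but_not_t4(self):
        p = profile([5, 0, 3, 2, 0])
        assert p.run_len == 1
        assert np.array_equal(p.t4, [5, 0, 3, 2])
        assert p.N == 3

    def test_all_zero(self):
        p = profile([0, 0, 0, 0, 0])
        assert p.run_len == 0 and p.N == 0

    def test_short_lines_pad_with_zero(self):
        p = profile([2, 1])
        assert np.array_equal(p.t4, [2, 1, 0, 0])

    def test_rear_direction_mirrors_coordinates(self):
        z = np.zeros((3, 7))
        z[1] = [1, 2, 3, 9, 4, 5, 6]
        rg = RotatedGrid(xlevels=np.arange(7) - 3.0, ylevels=np.array([-1.0, 0, 1]), z=z)
        front = line_profile(rg, 0.0, "front")
        rear = line_profile(rg, 0.0, "rear")
        assert np.array_equal(front.zs, [9, 4, 5, 6])
        assert np.array_equal(rear.zs, [9, 3, 2, 1])
        assert np.array_equal(rear.xs, [0, 1, 2, 3])
        assert front.opposite_z == 3 and rear.opposite_z == 4


class TestFitBest:
    def test_half_circle_boundary_near_radius(self):
        xs = np.arange(5.0)
        p = profile(np.sqrt(25 - xs**2))
        ivals, prov, _ = fit_best(p)
        a, b = ivals[0]
        assert a == 0.0
        # the least-squares cubic through the 5 samples crosses zero a bit
        # beyond the radius; verified against an independent normal-equations
        # fit + dense sign scan (root 5.753)
        V = np.vander(xs, 4)
        ref = np.linalg.solve(V.T @ V, V.T @ p.zs)
        grid = np.linspace(1e-9, 10, 1_000_001)
        vals = np.polyval(ref, grid)
        scan_root = grid[np.nonzero(np.diff(np.sign(vals)))[0][0]]
        assert b == pytest.approx(scan_root, abs=1e-4)
        assert 4.5 <= b <= 6.0

    def test_linear_profile_recovers_exact_root(self):
        p = profile([5, 4, 3, 2, 1])
        (ivals, prov, _) = fit_best(p)
        assert ivals[0][1] == pytest.approx(5.0, abs=1e-6)

    def test_constant_profile_falls_back_past_run(self):
        p = profile([1, 1, 1, 1, 1])
        ivals, prov, _ = fit_best(p)
        assert prov == ["fallback"]
        assert ivals[0][1] == pytest.approx(4.5)

    def test_zero_residual_polynomial_recovery(self):
        # samples of (x-6)(x^2+1)/(-43.2): cubic with smallest positive root 6
        coeffs = np.poly([6.0, 1j, -1j]).real * -1 / 43.2
        xs = np.arange(6.0)
        p = profile(np.polyval(coeffs, xs))
        assert p.run_len == 6
        ivals, prov, _ = fit_best(p)
        assert prov == ["fitBest"]
        assert ivals[0][1] == pytest.approx(6.0, abs=1e-6)

    def test_boundary_invariant_under_height_scaling(self, rng):
        for _ in range(10):
            zs = np.sort(rng.uniform(0.5, 5, 7))[::-1]
            p1, p2 = profile(zs), profile(7.5 * zs)
            b1, _, _ = fit_best(p1)
            b2, _, _ = fit_best(p2)
            assert b1[0][1] == pytest.approx(b2[0][1], rel=1e-6)

    def test_least_squares_matches_normal_equations_oracle(self, rng):
        from somabda.soma_contour import _polyfit

        for _ in range(20):
            r = rng.integers(5, 10)
            xs = np.arange(r, dtype=float)
            zs = rng.uniform(0.5, 5, r)
            coeffs = _polyfit(xs, zs, 3)
            V = np.vander(xs, 4)
            ref = np.linalg.solve(V.T @ V, V.T @ zs)
            assert np.allclose(coeffs, ref, atol=1e-8)

    def test_selected_roots_match_dense_sign_scan(self, rng):
        from somabda.soma_contour import _polyfit, _smallest_positive_root

        for _ in range(30):
            coeffs = rng.uniform(-2, 2, 4)
            root = _smallest_positive_root(coeffs)
            xs = np.linspace(1e-9, 60, 2_000_001)
            vals = np.polyval(coeffs, xs)
            sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
            if root is not None and root < 60:
                assert sign_changes.size > 0
                scan_root = xs[sign_changes[0]]
                assert root == pytest.approx(scan_root, abs=1e-4)
            elif sign_changes.size > 0:
                # a sign change the root finder missed would be a defect,
                # unless the polynomial only touches zero (double root)
                scan_root = xs[sign_changes[0]]
                assert root is not None and root == pytest.approx(scan_root, abs=1e-4)


class TestSpecialCases:
    # one nonzero pixel: parabola through it with zeros one step either side
    @pytest.mark.parametrize(
        "t4,expected",
        [
            ([0, 2, 0, 0], [(0.0, 2.0)]),   # u=2
            ([0, 0, 0, 2], []),             # u=4: cropped
            ([2, 0, 0, 0], [(0.0, 1.0)]),   # u=1: clipped at the origin
        ],
    )
    def test_one_point(self, t4, expected):
        ivals, _ = fit_one_point(profile(t4))
        assert [(pytest.approx(a), pytest.approx(b)) for a, b in ivals] == expected

    @pytest.mark.parametrize(
        "t4,expected",
        [
            ([0, 2, 1, 0], [(0.0, 3.0)]),   # adjacent pair, flanking zeros
            ([0, 0, 2, 1], []),             # pair at (3,4) detached: cropped
            ([2, 0, 1, 0], [(0.0, 1.0)]),   # v-u>1: one-point rule on the first
        ],
    )
    def test_two_points(self, t4, expected):
        ivals, _ = fit_two_points(profile(t4))
        assert [(pytest.approx(a), pytest.approx(b)) for a, b in ivals] == expected

    def test_three_points_zero_at_far_end_linear_data(self):
        # heights 3,2,1,0: the interpolating cubic through all four is the
        # line 3 - x, so the boundary is its root x = 3
        ivals, prov = fit_three_points(profile([3, 2, 1, 0]))
        assert prov == ["threePoints"]
        assert ivals[0][0] == 0.0
        assert ivals[0][1] == pytest.approx(3.0, abs=1e-9)

    def test_three_points_middle_zero_unions_handlers(self):
        ivals, _ = fit_three_points(profile([2, 0, 1, 1]))
        # one-point on position 1 gives [0,1]; the attached pair (3,4) gives
        # [1,4]; together they cover [0,4]
        assert ivals == [(0.0, 1.0), (1.0, 4.0)]

    def test_three_points_zero_at_origin_detached(self):
        # cubic through (0,0),(1,1),(2,2),(3,1) has positive root (3+sqrt(13))/2
        ivals, _ = fit_three_points(profile([0, 1, 2, 1]))
        assert ivals[0][1] == pytest.approx((3 + np.sqrt(13)) / 2, abs=1e-9)

    def test_three_points_zero_at_origin_attached_uses_opposite_height(self):
        attached = fit_three_points(profile([0, 1, 2, 1], opposite_z=2.0))[0]
        detached = fit_three_points(profile([0, 1, 2, 1], opposite_z=0.0))[0]
        assert attached[0][1] != pytest.approx(detached[0][1], abs=1e-6)

    def test_three_points_far_zero_attached_branch(self):
        p = profile([3, 2, 1, 0], opposite_z=3.5)
        ivals, _ = fit_three_points(p)
        # cubic through (-1, 3.5), (0,3), (1,2), (2,1) crosses zero beyond 2
        assert ivals[0][1] > 2.0


class TestLineBoundary:
    def test_dispatch_covers_all_pixel_counts(self):
        rows = {
            -2.0: [0, 0, 0, 0, 0, 0, 0, 0, 0],
            -1.0: [0, 0, 0, 0, 2, 0, 0, 0, 0],
            0.0: [0, 1, 2, 4, 5, 4, 2, 1, 0],
            1.0: [0, 0, 0, 2, 3, 2, 0, 0, 0],
            2.0: [0, 0, 0, 0, 0, 0, 1, 0, 0],
        }
        rg = make_rgrid(rows)
        for yp in rg.ylevels:
            for direction in ("front", "rear"):
                lb = line_boundary(rg, yp, direction)
                for a, b in lb.intervals:
                    assert 0.0 <= a <= b

    def test_empty_line_has_empty_boundary(self):
        rg = make_rgrid({-1.0: [0] * 9, 0.0: [0, 0, 1, 2, 3, 2, 1, 0, 0], 1.0: [0] * 9})
        lb = line_boundary(rg, -1.0, "front")
        assert lb.intervals == ()

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 8), min_size=5, max_size=12), st.floats(0, 5))
    def test_never_aborts(self, zs, opp):
        lb_in = profile(zs, opposite_z=opp)
        rg = make_rgrid({0.0: list(reversed(zs)) + [9.0] + list(zs)})
        for direction in ("front", "rear"):
            lb = line_boundary(rg, 0.0, direction)
            for a, b in lb.intervals:
                assert np.isfinite(a) and np.isfinite(b) and a <= b


class TestSomaRegion:
    def test_hemisphere_region_covers_support_and_volume_matches(self, hemisphere):
        report, view, region = bda_report_norot(hemisphere, PHANTOM_CFG)
        assert np.all(region.mask[view.z > 0])
        assert report.V_total == pytest.approx(v_sum(hemisphere), rel=1e-12)

    def test_extension_pixels_beyond_roots_excluded(self, hemisphere_with_extensions):
        _, view, region = bda_report_norot(hemisphere_with_extensions, PHANTOM_CFG)
        # the strip runs to the frame borders, but the delimited soma must not
        strip_rows = np.abs(view.ylevels + 0.0)  # ylevels centred at C90
        far_cols = np.abs(view.xlevels) > 10
        assert not region.mask[:, far_cols].any()

    def test_mirror_symmetric_phantom_gives_mirror_symmetric_mask(self, hemisphere_with_extensions):
        _, view, region = bda_report_norot(hemisphere_with_extensions, PHANTOM_CFG)
        assert np.array_equal(region.mask, region.mask[:, ::-1])
        assert np.array_equal(region.mask, region.mask[::-1, :])
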