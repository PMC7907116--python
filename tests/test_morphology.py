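"""Laplace thickness and Menger tortuosity: analytic geometries, sparse
oracle, invariances."""

import numpy as np
import pytest

from octdr.morphology import (bin_profile, layer_boundary_polylines,
                              layer_thickness_profile, layer_tortuosity_marker,
                              menger_curvature, menger_tortuosity,
                              solve_laplace, trace_thickness)


def flat_slab(H=20, W=30, top=5, d=10):
    mask = np.zeros((H, W), bool)
    mask[top:top + d + 1, :] = True
    up = np.zeros((H, W), bool)
    up[top, :] = True
    lo = np.zeros((H, W), bool)
    lo[top + d, :] = True
    return mask, up, lo


class TestLaplace:
    def test_flat_slab_linear_potential(self):
        mask, up, lo = flat_slab()
        f = solve_laplace(mask, up, lo, tol=1e-6)
        rows = np.arange(5, 16)
        expected = (rows - 5) / 10.0
        np.testing.assert_allclose(f.gamma[5:16, 10], expected, atol=1e-4)

    def test_maximum_principle(self):
        rng = np.random.default_rng(0)
        mask = rng.random((25, 25)) < 0.9
        mask[:3] = False
        mask[-3:] = False
        up = np.zeros_like(mask)
        lo = np.zeros_like(mask)
        up[3, :] = mask[3, :]
        lo[21, :] = mask[21, :]
        mask |= up | lo
        f = solve_laplace(mask, up, lo, tol=1e-5)
        vals = f.gamma[np.isfinite(f.gamma)]
        assert vals.min() >= -1e-12 and vals.max() <= 1 + 1e-12

    def test_looser_tolerance_never_smaller_residual(self):
        mask, up, lo = flat_slab()
        f_tight = solve_laplace(mask, up, lo, tol=1e-6)
        f_loose = solve_laplace(mask, up, lo, tol=2e-6)
        assert f_loose.residual >= f_tight.residual

    def test_nonconvergence_raises_with_residual(self):
        mask, up, lo = flat_slab()
        with pytest.raises(RuntimeError, match="residual"):
            solve_laplace(mask, up, lo, tol=1e-12, max_iter=3)

    def test_jacobi_matches_direct_sparse_solve(self):
        """Oracle equivalence with a direct solve of the same discrete
        Laplacian on random slab-like masks."""
        from tests_support import sparse_laplace_solution

        rng = np.random.default_rng(1)
        for _ in range(3):
            H = W = 30
            top = int(rng.integers(2, 6))
            d = int(rng.integers(8, 16))
            mask, up, lo = flat_slab(H, W, top, d)
            # carve a couple of obstacle holes
            holes = rng.random((H, W)) < 0.02
            interior = mask & ~up & ~lo & ~holes
            f = solve_laplace(interior | up | lo, up, lo, tol=1e-7)
            direct = sparse_laplace_solution(interior, up, lo)
            np.testing.assert_allclose(f.gamma[interior], direct, atol=1e-4)


class TestThickness:
    def test_flat_slab_thickness_exact(self):
        mask, up, lo = flat_slab(d=10)
        f = solve_laplace(mask, up, lo, tol=1e-6)
        t = np.array([p.thickness for p in trace_thickness(f, n_seeds=20)])
        np.testing.assert_allclose(t, 10.0, atol=0.1)

    def test_tilted_slab_recovers_normal_separation(self):
        """A 30-degree slab yields the normal separation d, not the larger
        vertical chord d / cos(30)."""
        d = 20.0
        theta = np.deg2rad(30)
        v = d / np.cos(theta)
        H, W = 110, 120
        mask = np.zeros((H, W), bool)
        up = np.zeros((H, W), bool)
        lo = np.zeros((H, W), bool)
        for c in range(W):
            r0 = 5 + np.tan(theta) * c
            r1 = r0 + v
            if r1 >= H - 1:
                continue
            mask[int(round(r0)):int(round(r1)) + 1, c] = True
            up[int(round(r0)), c] = True
            lo[int(round(r1)), c] = True
        f = solve_laplace(mask, up, lo, tol=1e-6)
        t = np.array([p.thickness for p in trace_thickness(f, n_seeds=40)])
        t = t[5:-5]  # edge streamlines leave the short slab ends
        assert t.mean() == pytest.approx(d, rel=0.02)
        assert abs(t.mean() - v) / v > 0.1  # clearly not the vertical chord

    def test_annulus_recovers_radial_separation(self):
        r1, r2 = 12.0, 24.0
        H = W = 64
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        rad = np.hypot(rr - 31.5, cc - 31.5)
        mask = (rad >= r1 - 0.5) & (rad <= r2 + 0.5)
        up = (rad >= r1 - 0.5) & (rad < r1 + 0.5)
        lo = (rad > r2 - 0.5) & (rad <= r2 + 0.5)
        with pytest.warns(UserWarning, match="holes"):
            f = solve_laplace(mask, up, lo, tol=1e-6)
        t = np.array([p.thickness for p in trace_thickness(f, n_seeds=60)])
        assert t.mean() == pytest.approx(r2 - r1, rel=0.02)

    @pytest.mark.parametrize("angle", [0.0, 15.0, 30.0])
    def test_rotation_invariance(self, angle):
        d = 24.0
        theta = np.deg2rad(angle)
        v = d / np.cos(theta)
        H, W = 130, 140
        mask = np.zeros((H, W), bool)
        up = np.zeros((H, W), bool)
        lo = np.zeros((H, W), bool)
        for c in range(W):
            r0 = 5 + np.tan(theta) * c
            r1 = r0 + v
            if r1 >= H - 1:
                continue
            mask[int(round(r0)):int(round(r1)) + 1, c] = True
            up[int(round(r0)), c] = True
            lo[int(round(r1)), c] = True
        f = solve_laplace(mask, up, lo, tol=1e-6)
        t = np.array([p.thickness for p in trace_thickness(f, n_seeds=40)])
        assert t[5:-5].mean() == pytest.approx(d, rel=0.02)


class TestMenger:
    def test_unit_circle_triplet(self):
        assert menger_curvature((0, 1), (1, 0), (0, -1)) == pytest.approx(
            1.0, abs=1e-9)

    def test_collinear_zero(self):
        assert menger_curvature((0, 0), (1, 0), (2, 0)) == 0.0
        assert menger_curvature((0, 0), (0, 0), (2, 0)) == 0.0

    def test_radius_2_circle_sampled_anywhere(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b, c = rng.uniform(0, 2 * np.pi, 3)
            pts = [(2 * np.cos(t), 2 * np.sin(t)) for t in (a, b, c)]
            if len({tuple(np.round(p, 9)) for p in pts}) < 3:
                continue
            assert menger_curvature(*pts) == pytest.approx(0.5, abs=1e-9)

    def test_permutation_and_rigid_motion_invariance(self):
        import itertools
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, (3, 2))
        k0 = menger_curvature(*pts)
        for perm in itertools.permutations(range(3)):
            assert menger_curvature(*pts[list(perm)]) == pytest.approx(
                k0, abs=1e-12)
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + np.array([11.0, -3.0])
        assert menger_curvature(*moved) == pytest.approx(k0, abs=1e-9)

    def test_sinusoid_peak_curvature(self):
        a, lam = 5.0, 100.0
        x = np.arange(400, dtype=float)
        poly = np.column_stack([a * np.sin(2 * np.pi * x / lam), x])
        kappa = menger_tortuosity(poly, window=5)
        assert kappa.shape == (400 - 10,)
        assert kappa.max() == pytest.approx(a * (2 * np.pi / lam) ** 2,
                                            rel=0.10)

    def test_straight_boundary_zero_profile(self):
        poly = np.column_stack([np.full(50, 7.0), np.arange(50.0)])
        kappa = menger_tortuosity(poly, window=5)
        np.testing.assert_allclose(kappa, 0.0, atol=1e-12)

    def test_window_too_large_raises(self):
        with pytest.raises(ValueError, match="window"):
            menger_tortuosity(np.zeros((8, 2)), window=5)


class TestLayerMarkers:
    def test_tortuosity_marker_concatenates_boundaries(self):
        x = np.arange(120, dtype=float)
        up = np.column_stack([10 + np.sin(x / 10), x])
        lo = np.column_stack([30 + np.sin(x / 10), x])
        m = layer_tortuosity_marker(up, lo, n_bins=10)
        assert m.values.shape == (20,)
        np.testing.assert_allclose(m.values[:10], m.values[10:], atol=1e-9)

    def test_missing_boundary_warns_and_uses_remaining(self):
        x = np.arange(60, dtype=float)
        up = np.column_stack([np.full(60, 5.0), x])
        with pytest.warns(UserWarning, match="missing boundary"):
            m = layer_tortuosity_marker(up, None, n_bins=5)
        assert m.values.shape == (5,)

    def test_thickness_profile_on_phantom_onl(self, noiseless_scan):
        prof = layer_thickness_profile(noiseless_scan.truth_labels, 6,
                                       n_bins=10)
        vals = prof.finite_values()
        counts = (noiseless_scan.truth_labels == 6).sum(axis=0)
        assert vals.size > 0
        assert abs(np.median(vals) - np.median(counts)) < 2.0

    def test_bin_profile_nan_policy(self):
        out = bin_profile(np.array([1.0, np.nan, 3.0, np.nan]), 2)
        np.testing.assert_allclose(out, [1.0, 3.0])

    def test_boundary_polylines_absent_layer(self):
        up, lo = layer_boundary_polylines(np.zeros((10, 10), int), 3)
        assert up is None and lo is None
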