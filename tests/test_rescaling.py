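import numpy as np
import pytest
from shapely.geometry import Polygon

import morphodyn as md
from conftest import FnMap, rect_outline
from morphodyn.datamodel import TissueOutline, lattice_in_polygon
from morphodyn.rescaling import (centroid_size, decompose,
                                 interspecies_scaling,
                                 mean_deformation_gradient, pseudo_map,
                                 resample_ring, star_domain_residual,
                                 transform_points_to_xi)


class TestCentroidSize:
    def test_unit_circle(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ring = np.column_stack([np.cos(th), np.sin(th)])
        assert centroid_size(ring) == pytest.approx(1.0, abs=1e-3)

    def test_homogeneity(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ring = np.column_stack([2 * np.cos(th), np.sin(th) - 0.3 * np.cos(2 * th)])
        assert centroid_size(5.0 * ring) == pytest.approx(5.0 * centroid_size(ring),
                                                          rel=1e-12)

    def test_ellipse_against_dense_sampling(self):
        """M=200 equal-arc-length samples agree with a dense refinement."""
        th = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        ring = np.column_stack([2 * np.cos(th), np.sin(th)])
        coarse = centroid_size(ring, M=200)
        dense = centroid_size(ring, M=100_000)
        assert coarse == pytest.approx(dense, abs=1e-3)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            resample_ring(np.zeros((4, 2)), 10)


class TestMeanGradient:
    def test_affine_map_exact(self):
        A = np.array([[1.5, 0.2], [0.0, 0.8]])
        m = FnMap(lambda X, t: X @ A.T, [0, 1], rect_outline())
        Fbar = mean_deformation_gradient(m, m.initial_domain, 1.0)
        np.testing.assert_allclose(Fbar, A, atol=1e-8)

    def test_identity(self):
        m = FnMap(lambda X, t: X, [0, 1], rect_outline())
        np.testing.assert_allclose(mean_deformation_gradient(m, m.initial_domain, 0.5),
                                   np.eye(2), atol=1e-9)

    def test_spatially_varying_converges_with_refinement(self, smooth_growth_map):
        m = smooth_growth_map
        coarse = mean_deformation_gradient(m, m.initial_domain, 3.0, spacing=25)
        fine = mean_deformation_gradient(m, m.initial_domain, 3.0, spacing=2.5)
        assert np.abs(coarse - fine).max() < 1e-4


class TestDecomposition:
    def test_recombination_identity(self, decomposed_species_A):
        """L(t) xi + xbar(t) reproduces phi to better than 1e-9 um."""
        map_A, growth, dyn = decomposed_species_A
        seeds = dyn.seeds[::7]
        xi = dyn.trajectories(seeds)
        phi = map_A.trajectory(growth.X_of_xi0(seeds), growth.stages)
        rec = np.einsum("tij,ntj->nti", growth.L, xi) + growth.centroid[None]
        assert np.abs(rec - phi).max() < 1e-9

    def test_uniform_growth_gives_zero_flow(self):
        """Spatially uniform (even anisotropic) growth: xi is frozen and the
        velocity field vanishes below 1e-8."""
        def fn(X, t):
            return X @ np.diag([1 + 0.3 * t, 1 + 0.1 * t]) + np.array([5.0, 2.0]) * t
        m = FnMap(fn, np.linspace(0, 5, 11), rect_outline())
        growth, dyn = decompose(m, seed_spacing=0.1)
        assert np.abs(dyn.xi - dyn.xi[:, :1]).max() < 1e-10
        assert np.abs(dyn.velocity(dyn.seeds[::5])).max() < 1e-8

    def test_pure_translation_keeps_xi_constant(self):
        m = FnMap(lambda X, t: X + np.array([30.0, -10.0]) * t,
                  np.linspace(0, 4, 9), rect_outline())
        growth, dyn = decompose(m, seed_spacing=0.1)
        assert np.abs(dyn.xi - dyn.xi[:, :1]).max() < 1e-10

    def test_velocity_matches_trajectory_derivative(self):
        """Evaluating the xi equation of motion agrees with the time
        derivative of xi trajectories at second order in the stage step."""
        from conftest import analytic_nonlinear_map
        errs = []
        for n_stages in (17, 33):
            m = analytic_nonlinear_map(stages=np.linspace(0.0, 4.0, n_stages))
            growth, dyn = md.decompose(m, seed_spacing=0.25)
            seeds = dyn.seeds
            v = dyn.velocity(seeds)
            dxi = np.gradient(dyn.trajectories(seeds), growth.stages, axis=1)
            errs.append(np.abs(v - dxi)[:, 2:-2].max())
        assert errs[1] < 1e-3
        assert errs[1] < errs[0] / 2.5   # ~2nd-order shrinkage

    def test_frame_covariance(self, species_pair):
        """Rotating all physical coordinates rotates L and leaves xi
        trajectories unchanged."""
        _, map_A, _ = species_pair
        th = 0.4
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        stages = map_A.stage_grid.stages

        rot_outline = TissueOutline(map_A.initial_domain.stage,
                                    Polygon(map_A.initial_domain.vertices @ Q.T))

        class Rotated:
            stage_grid = map_A.stage_grid
            initial_domain = rot_outline
            t0 = map_A.t0

            def trajectory(self, X, ss):
                return map_A.trajectory(np.atleast_2d(X) @ Q, ss) @ Q.T

            def gradient_trajectory(self, X, ss):
                pos, F = map_A.gradient_trajectory(np.atleast_2d(X) @ Q, ss)
                return pos @ Q.T, np.einsum("ij,ntjk,kl->ntil", Q, F, Q.T)

        g0, d0 = md.decompose(map_A, stages=stages, seed_spacing=0.15)
        g1, d1 = md.decompose(Rotated(), stages=stages, seed_spacing=0.15)
        # full-frame rotation conjugates the growth tensor: L -> Q L Q^T
        np.testing.assert_allclose(g1.L, np.einsum("ij,tjk,lk->til", Q, g0.L, Q),
                                   atol=0.5)  # um; ~0.1% of tissue size
        # same seeds expressed in the rotated frame trace the same xi paths
        seeds = d0.seeds[::9]
        xi0 = d0.trajectories(seeds)
        xi1 = d1.trajectories(seeds @ Q.T)
        np.testing.assert_allclose(xi1, np.einsum("ntj,ij->nti", xi0, Q), atol=2e-3)


class Test1DReduction:
    def test_matches_scalar_closed_form(self):
        """A 1D growth profile embedded on axis 1 reproduces the scalar
        rescaled equation of motion dxi/dt = (S_X - S) xi - v_g, computed
        independently with scalar arithmetic."""
        a0, a2 = 0.08, 0.004

        def fn(X, t):
            g = 1 + (a0 + a2 * X[:, 0] ** 2 / 100**2) * t
            return np.column_stack([g * X[:, 0], X[:, 1]])

        stages = np.linspace(0.0, 4.0, 17)
        outline = rect_outline(400, 200)
        m = FnMap(fn, stages, outline, h=0.5)
        growth, dyn = decompose(m, quad_spacing=16.0, seed_spacing=0.12)
        seeds = dyn.seeds[::11]
        v = dyn.velocity(seeds)

        # independent scalar computation on the same quadrature abscissae
        pts = lattice_in_polygon(outline.polygon, 16.0)
        x1 = pts[:, 0]
        nodes, wts = np.polynomial.legendre.leggauss(16)
        eps = 0.5 * (nodes + 1)
        w = 0.5 * wts

        def F1(x, t):       # d x1 / d X1 of the scalar profile
            return 1 + (a0 + 3 * a2 * x**2 / 100**2) * t

        Fb = np.array([F1(x1, t).mean() for t in stages])
        Sb = np.gradient(Fb, stages) / Fb
        X1s = growth.X_of_xi0(seeds)[:, 0]
        for i, Xs in enumerate(X1s):
            G = np.array([(w * F1(eps * Xs, t)).sum() for t in stages])
            SX = np.gradient(G, stages) / G
            xi1 = dyn.trajectories(seeds[i:i + 1])[0, :, 0]
            rhs = (SX - Sb) * xi1          # v_g = 0 by symmetry of the profile
            np.testing.assert_allclose(v[i, 2:-2, 0], rhs[2:-2], atol=1e-6)
        # nothing moves on the passive axis
        assert np.abs(v[:, 2:-2, 1]).max() < 1e-8


class TestStarDomain:
    def test_affine_exact(self):
        A = np.array([[1.4, 0.3], [0.1, 0.9]])
        m = FnMap(lambda X, t: X @ A.T, [0, 1], rect_outline())
        X = np.array([[150.0, 80.0], [-200.0, -90.0]])
        assert star_domain_residual(m, X, 1.0).max() < 1e-8

    def test_smooth_synthetic_map_small_residual(self, smooth_growth_map):
        """64-point quadrature reproduces positions within 1e-5 um, with at
        least 2nd-order improvement under refinement."""
        m = smooth_growth_map
        pts = np.array([[250.0, 150.0], [-280.0, -170.0], [100.0, -180.0]])
        r64 = star_domain_residual(m, pts, 3.5, n_quad=64).max()
        r4 = star_domain_residual(m, pts, 3.5, n_quad=4).max()
        assert r64 < 1e-5
        assert r64 <= r4 / 4

    def test_segment_exit_raises(self, smooth_growth_map):
        m = smooth_growth_map
        with pytest.raises(ValueError, match="star"):
            star_domain_residual(m, np.array([[500.0, 300.0]]), 1.0)


class TestPseudoMap:
    def test_same_species_same_time_identity(self, decomposed_species_A):
        map_A, growth, dyn = decomposed_species_A
        seeds = dyn.seeds[::13]
        t = growth.stages[6]
        ps = pseudo_map(growth, dyn, seeds, t, t)
        rec = dyn.trajectories(seeds)[:, 6] @ growth.L[6].T + growth.centroid[6]
        np.testing.assert_allclose(ps, rec, atol=1e-12)

    def test_seed_outside_domain_flagged(self, decomposed_species_A):
        _, growth, dyn = decomposed_species_A
        far = np.array([[5.0, 5.0]])
        out = pseudo_map(growth, dyn, far, growth.stages[2], growth.stages[2])
        assert np.isnan(out).all()


class TestScalingOperator:
    def test_identical_species(self, decomposed_species_A):
        _, growth, _ = decomposed_species_A
        t = growth.stages[5]
        op = interspecies_scaling(growth, growth, t)
        np.testing.assert_allclose(op.M, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(op.U, np.eye(2), atol=1e-12)

    def test_planted_diagonal_stretch(self, decomposed_species_A):
        from morphodyn.rescaling import MeanGrowth
        _, growth, _ = decomposed_species_A
        D = np.diag([2.0, 1.0])
        gA = MeanGrowth(growth.stages, growth.C0,
                        np.einsum("ij,tjk->tik", D, growth.Fbar), growth.centroid)
        op = interspecies_scaling(gA, growth, growth.stages[4])
        np.testing.assert_allclose(op.U, D, atol=1e-9)
        np.testing.assert_allclose(op.R, np.eye(2), atol=1e-9)

    def test_polar_recomposition_random_pair(self):
        from morphodyn.rescaling import MeanGrowth
        rng = np.random.default_rng(8)
        stages = np.linspace(0, 1, 3)
        mk = lambda: MeanGrowth(stages, 300.0, np.stack(
            [np.eye(2), np.eye(2) + 0.1 * rng.normal(size=(2, 2)),
             np.eye(2) + 0.2 * rng.normal(size=(2, 2))]), np.zeros((3, 2)))
        gA, gB = mk(), mk()
        op = interspecies_scaling(gA, gB, 1.0)
        np.testing.assert_allclose(op.R @ op.U, op.M, atol=1e-12)
        np.testing.assert_allclose(op.R.T @ op.R, np.eye(2), atol=1e-12)
        assert np.linalg.det(op.R) == pytest.approx(1.0)
        # U against an independent symmetric-square-root oracle
        from scipy.linalg import sqrtm
        np.testing.assert_allclose(op.U, sqrtm(op.M.T @ op.M), atol=1e-10)


class TestPointTransform:
    def test_centroid_maps_to_origin(self, decomposed_species_A):
        _, growth, _ = decomposed_species_A
        t = growth.stages[3]
        xi = transform_points_to_xi(growth.centroid_at(t)[None, :], growth, t)
        np.testing.assert_allclose(xi, 0.0, atol=1e-12)

    def test_isotropic_scaling(self):
        from morphodyn.rescaling import MeanGrowth
        stages = np.array([0.0, 1.0])
        g = MeanGrowth(stages, 2.0, np.stack([np.eye(2), 3 * np.eye(2)]),
                       np.array([[0.0, 0.0], [10.0, 4.0]]))
        p = np.array([[16.0, 10.0]])
        np.testing.assert_allclose(transform_points_to_xi(p, g, 1.0),
                                   (p - [10, 4]) / 6.0)

    def test_expression_footprint_time_invariant_under_uniform_growth(self):
        """A marker domain advected by uniform growth has a frozen
        xi-footprint."""
        def fn(X, t):
            return (1 + 0.5 * t) * X
        m = FnMap(fn, np.linspace(0, 3, 7), rect_outline())
        growth, _ = decompose(m, seed_spacing=0.2)
        blob = np.array([[50.0, 30.0], [80.0, -20.0], [120.0, 10.0]])
        xi_t = [transform_points_to_xi(fn(blob, t), growth, t)
                for t in growth.stages]
        for x in xi_t[1:]:
            np.testing.assert_allclose(x, xi_t[0], atol=1e-10)
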