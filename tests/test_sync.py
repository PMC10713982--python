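import numpy as np
import pytest
from shapely.geometry import Polygon

import morphodyn as md
from morphodyn import sync
from morphodyn.datamodel import lattice_in_polygon
from morphodyn.sync import (CompositeStageMap, TrajectoryDistanceMatrix,
                            composite_stage_maps, fit_linear_correspondence,
                            overlap_region, validity_range)


def square_xi(side=1.0, center=(0.0, 0.0)):
    c = np.asarray(center)
    h = side / 2
    return Polygon(c + np.array([[-h, -h], [h, -h], [h, h], [-h, h]]))


class TestOverlapRegion:
    def test_identical_outlines(self):
        poly, seeds = overlap_region(square_xi(), square_xi(), spacing=0.1)
        assert poly.area == pytest.approx(1.0)
        assert len(seeds) == 100

    def test_disjoint_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            overlap_region(square_xi(), square_xi(center=(5, 5)))

    def test_seed_count_matches_area_density(self):
        a = square_xi(1.0)
        b = square_xi(1.0, center=(0.415, 0.0))    # overlap 0.585 x 1
        poly, seeds = overlap_region(a, b, spacing=0.05)
        expected = poly.area / 0.05**2
        assert abs(len(seeds) - expected) <= poly.length / 0.05 + 1


class FrozenDyn:
    """Stand-in dynamics with prescribed xi trajectories (for metric tests)."""

    def __init__(self, fn, stages):
        self.fn = fn
        self.stages = np.asarray(stages, float)
        self.xi_outline = square_xi(2.0)

    def trajectories(self, seeds):
        seeds = np.atleast_2d(seeds)
        return np.stack([self.fn(seeds, t) for t in self.stages], axis=1)

    def at_stage(self, seeds, t):
        xi = self.trajectories(seeds)
        k = int(np.argmin(np.abs(self.stages - t)))
        return xi[:, k]


class TestTrajectoryDistance:
    stages = np.linspace(0, 1, 5)
    seeds = lattice_in_polygon(square_xi(1.0), 0.2)

    def test_identical_sets_give_zero_and_symmetry(self):
        d1 = FrozenDyn(lambda s, t: s * (1 + t), self.stages)
        d2 = FrozenDyn(lambda s, t: s * (1 + t), self.stages)
        assert sync.trajectory_distance(d1, d2, 0.5, 0.5, self.seeds) == 0.0
        d3 = FrozenDyn(lambda s, t: s * (1 + 2 * t), self.stages)
        ab = sync.trajectory_distance(d1, d3, 0.5, 0.75, self.seeds)
        ba = sync.trajectory_distance(d3, d1, 0.75, 0.5, self.seeds)
        assert ab == pytest.approx(ba)

    def test_constant_offset_gives_norm(self):
        d1 = FrozenDyn(lambda s, t: s, self.stages)
        d2 = FrozenDyn(lambda s, t: s + np.array([0.3, -0.4]), self.stages)
        assert sync.trajectory_distance(d1, d2, 0.5, 0.5, self.seeds) == pytest.approx(0.5)

    def test_pseudometric_triangle_inequality(self):
        rng = np.random.default_rng(11)
        snaps = [self.seeds + rng.normal(0, 0.2, self.seeds.shape) for _ in range(3)]
        d = lambda a, b: np.linalg.norm(a - b, axis=1).mean()
        assert d(snaps[0], snaps[2]) <= d(snaps[0], snaps[1]) + d(snaps[1], snaps[2]) + 1e-12

    def test_conserved_species_pair_matches(self, species_pair):
        """Two species built from one flow agree in xi at equal archetype
        times to integrator precision."""
        _, map_A, map_B = species_pair
        tauj = np.linspace(0, 9, 10)
        gA, dA = md.decompose(map_A, stages=map_A.spec.stage_of(tauj), seed_spacing=0.15)
        gB, dB = md.decompose(map_B, stages=map_B.spec.stage_of(tauj), seed_spacing=0.15)
        _, seeds = overlap_region(dA.xi_outline, dB.xi_outline, spacing=0.15)
        for j in (2, 5, 9):
            delta = sync.trajectory_distance(
                dA, dB, float(map_A.spec.stage_of(tauj[j])),
                float(map_B.spec.stage_of(tauj[j])), seeds)
            assert delta < 5e-3


class TestDistanceMatrixAndMaps:
    def test_zero_diagonal_and_identity_maps(self):
        stages = np.linspace(0, 1, 6)
        d1 = FrozenDyn(lambda s, t: s * (1 + t), stages)
        d2 = FrozenDyn(lambda s, t: s * (1 + t), stages)
        seeds = lattice_in_polygon(square_xi(1.0), 0.2)
        mat = sync.distance_matrix(d1, d2, seeds)
        assert np.allclose(np.diag(mat.delta), 0)
        ab, ba = composite_stage_maps(mat)
        np.testing.assert_array_equal(ab.target_stages, stages)
        np.testing.assert_array_equal(ba.target_stages, stages)
        tA_end, tB_end = validity_range(ab, ba)
        assert tA_end == stages[-1] and tB_end == stages[-1]

    def test_planted_linear_warp_ridge(self):
        """With dynamics B(t) = A(2t - 1), the argmin ridge of the distance
        matrix follows t_B = (t_A + 1) / 2 within a grid step."""
        stages_A = np.linspace(0, 1, 11)
        stages_B = np.linspace(-1, 1, 21)
        flow = lambda s, tau: s * (1 + tau) + np.array([0.3, 0.1]) * tau**2
        dA = FrozenDyn(flow, stages_A)
        dB = FrozenDyn(lambda s, t: flow(s, (t + 1) / 2), stages_B)
        seeds = lattice_in_polygon(square_xi(1.0), 0.15)
        mat = sync.distance_matrix(dA, dB, seeds)
        ab, _ = composite_stage_maps(mat)
        expected = 2 * stages_A - 1
        assert np.abs(ab.target_stages - expected).max() <= ab.step_target + 1e-12
        slope, intercept, resid = fit_linear_correspondence(ab)
        assert slope == pytest.approx(2.0, rel=0.02)
        assert abs(intercept - (-1.0)) <= ab.step_target
        assert resid <= ab.step_target

    def test_identity_correspondence_fit(self):
        cm = CompositeStageMap("AtoB", np.linspace(0, 1, 8), np.linspace(0, 1, 8),
                               np.linspace(0, 1, 8))
        slope, intercept, resid = fit_linear_correspondence(cm)
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0)
        assert resid < 1e-12


class TestValidityRange:
    def _mat(self, delta, sA, sB):
        return TrajectoryDistanceMatrix(np.asarray(sA, float), np.asarray(sB, float),
                                        delta, np.zeros((1, 2)))

    def test_jump_ends_range(self):
        s = np.linspace(0, 1, 11)
        targets = s.copy()
        targets[7:] += 0.3      # 3-step jump at index 7
        ab = CompositeStageMap("AtoB", s, targets, s)
        ba = CompositeStageMap("BtoA", s, s, s)
        tA_end, _ = validity_range(ab, ba, tol=1.0)
        assert tA_end <= s[7]

    def test_divergent_flows_truncate_range(self, species_pair):
        """A species-specific flow perturbation switched on at tau* breaks
        the correspondence within about two grid steps of tau*."""
        from dataclasses import replace
        from morphodyn.synthetic import GroundTruthMap, species_A_spec
        flow, _, _ = species_pair
        tau_star = 5.0
        mA = GroundTruthMap(flow, species_A_spec(warp_a=1.0, warp_b=0.0))
        specB = replace(species_A_spec(name="div", warp_a=1.0, warp_b=0.0,
                                       c0_scale=800.0),
                        divergence_onset=tau_star, divergence_strength=0.3,
                        divergence_seed=3)
        mB = GroundTruthMap(flow, specB)
        dyns = []
        for gt in (mA, mB):
            _, dyn = md.decompose(gt, stages=md.refine_stage_grid(gt.stage_grid, 2),
                                  seed_spacing=0.12)
            dyns.append(dyn)
        _, seeds = overlap_region(dyns[0].xi_outline, dyns[1].xi_outline, spacing=0.1)
        mat = sync.distance_matrix(dyns[0], dyns[1], seeds)
        ab, ba = composite_stage_maps(mat)
        tA_end, tB_end = validity_range(ab, ba, tol=1.0)
        step = ab.step_source
        assert abs(tA_end - tau_star) <= 2 * step + 1e-9
        assert abs(tB_end - tau_star) <= 2 * step + 1e-9


class TestInitialStageSelection:
    def test_planted_offset_recovered(self, species_pair):
        """With both species on one archetype time axis, re-referencing one
        species two stages late is detected: the matching initial pair wins."""
        from morphodyn.deformation import RebasedMap
        from morphodyn.regions import RegionComparer
        from morphodyn.rescaling import FieldCache
        flow, _, _ = species_pair
        from morphodyn.synthetic import GroundTruthMap, species_A_spec, species_B_spec
        mA = GroundTruthMap(flow, species_A_spec(warp_a=1.0, warp_b=0.0))
        mB = GroundTruthMap(flow, species_B_spec(warp_a=1.0, warp_b=0.0))
        t_star = 2.0

        def build(t0_A, t0_B):
            mAr = RebasedMap(mA, t0_A) if t0_A > mA.t0 else mA
            mBr = RebasedMap(mB, t0_B) if t0_B > mB.t0 else mB
            cache = FieldCache(mAr, mAr.initial_domain,
                               md.refine_stage_grid(mAr.stage_grid, 2))
            _, dC = md.decompose(mBr, stages=md.refine_stage_grid(mBr.stage_grid, 2),
                                 seed_spacing=0.12)
            return RegionComparer(cache, dC, seed_spacing=0.12,
                                  region_seed_spacing=0.12)

        res = sync.select_initial_stages(
            build, candidates_A=[0.0, 1.0, 2.0, 3.0], candidates_B=[t_star],
            paramsets=[(1.0, -20.0), (1.0, 20.0), (0.95, -20.0), (0.95, 20.0)],
            theta_grid=[-0.1, 0.0, 0.1])
        assert res["best"] == (t_star, t_star)
        medians = {r["t0_A"]: r["median"] for r in res["table"]}
        assert medians[t_star] == min(medians.values())
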