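# morphodyn

Comparative tissue morphodynamics for landmark-tracked 2D organ growth.

Developmental biologists who trace labeled cells in a growing tissue — the
motivating system is the vertebrate limb bud, imaged on its frontal plane —
face two obstacles when comparing morphogenesis between species: the
tissues differ in size and shape, and the species' staging scales do not
correspond. morphodyn implements a complete pipeline for this problem:

1. **Deformation-map reconstruction** — smooth per-interval maps
   x = φ(X, t) fitted from sparse labeled-spot correspondences (affine mean
   + Gaussian-process residual field), chained over consecutive stage
   intervals, with analytic deformation gradients F = ∂φ/∂X, Newton
   inversion, and bootstrap resampling.
2. **Rescaled (ξ-space) dynamics** — the decomposition
   φ(X, t) = L(t) ξ(ξ₀, t) + x̄(t), with L(t) = C₀F̄(t) the tensorial tissue
   size (initial centroid size × domain-averaged deformation gradient) and
   x̄(t) the area centroid. ξ-trajectories cancel average growth: under
   spatially uniform growth nothing moves in ξ, so they isolate the
   heterogeneous, biologically informative part of the dynamics. The ξ
   velocity field dξ/dt = L⁻¹(S̄_X − S̄)Lξ − v_g is evaluated directly.
3. **Developmental-clock synchronization** — the stage correspondence
   between two species is estimated by minimizing the mean ξ-trajectory
   distance δ(t_A, t_B) over a shared seed set; the package computes the
   full distance matrix, composite stage maps in both directions, their
   homeomorphic validity range, and a linear stage correspondence.
4. **Region comparison and overfitting control** — candidate sub-regions
   of one species' bud (parameterized by distal extent α, axis offset β,
   axis angle θ) are re-rescaled from scratch and compared via
   η(α, β, θ) (temporal mean of minimal δ); the coefficient of variation
   of the optimal angle across the β-grid, CV_β[θ*], flags overfitting.
5. **Synthetic two-species scenarios** — a first-class generator that
   drives both species with one archetype ξ-flow (a streamfunction
   circulation whose streamline is the bud outline, plus an A-P-asymmetric
   compressible term), species-specific growth schedules and stage warps,
   and a realistic measurement design (11 individuals with overlapping
   stage windows, ~10 µm spot noise), so every stage of the pipeline can be
   validated against ground truth.

## Worked example

```python
import numpy as np
import morphodyn as md
from morphodyn import sync

# two synthetic species driven by one archetype flow, species B twice the
# size with its own stage scale (t_B = tau + 21 vs t_A = 0.4 tau + 50.6)
flow, map_A, map_B = md.two_species_scenario(seed=1)

# simulate the labeling experiment for both species and reconstruct
# their composite maps from the noisy spot tables
dyns = []
for gt, seed in ((map_A, 11), (map_B, 12)):
    records = md.sample_spots(gt, md.uniform_design(150, seed=seed))
    fitted = md.reconstruct_map(records, gt.stage_grid, gt.initial_domain,
                                seed=seed)
    if seed == 11:
        print([round(m.fit_metadata["mean_residual"], 1)
               for m in fitted.interval_maps])
        # [19.0, 17.4, 18.9, 16.8, 17.7, 17.4, 18.6, 17.5, 16.5]
        # per-interval mean residual, um (sigma = 10 um on every measurement)
    growth, dyn = md.decompose(fitted,
                               stages=md.refine_stage_grid(gt.stage_grid, 3))
    dyns.append(dyn)
dyn_A, dyn_B = dyns
print(round(growth.C0, 1))   # 800.0 -- species B's initial centroid size, um

# synchronize the two staging scales by xi-trajectory matching
_, seeds = sync.overlap_region(dyn_A.xi_outline, dyn_B.xi_outline)
matrix = sync.distance_matrix(dyn_A, dyn_B, seeds)
ab, ba = sync.composite_stage_maps(matrix)
slope, intercept, resid = sync.fit_linear_correspondence(
    ab, (ab.source_stages[2], ab.source_stages[-3]))
print(round(slope, 2), round(resid, 2))
# 2.38  0.17
```

The recovered slope 2.38 (truth for this scenario: 2.5, i.e. species B's
stage axis runs 2.5x faster than A's per unit of shared developmental
progression) is read off the ridge of the trajectory-distance matrix; the
fitted line is the chart transition between the two staging scales on the
common developmental clock. Both species must be decomposed through the
same pipeline route -- the rescaled coordinates are only comparable under
one growth-estimator convention, and the sync functions warn otherwise.

A thin CLI mirrors the library (`morphodyn simulate`, `fit-maps`,
`decompose`, `sync`); run `morphodyn --help`.

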