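# Methods

## The model

morphodyn analyses landmark-based measurements of a growing planar tissue
(the motivating system is the vertebrate limb bud observed on its frontal
plane, with axis 1 proximo-distal and axis 2 antero-posterior, in µm). The
central object is the deformation map φ(X, t): the position at stage t of
the tissue material point initially at X. Everything else derives from it:

* the deformation gradient F(X, t) = ∂φ/∂X, whose determinant is the local
  area growth and whose right-stretch eigenstructure gives the magnitude
  (log λ₁/λ₂) and orientation of deformation anisotropy;
* the average growth factor L(t) = C₀ F̄(t), where C₀ is the initial
  centroid size of the outline and F̄(t) the domain-averaged deformation
  gradient — a tensorial "tissue size";
* the rescaled (ξ-space) position ξ(ξ₀, t) = L(t)⁻¹ (φ(X, t) − x̄(t)), with
  x̄(t) the area centroid of the deformed domain and ξ₀ = (X − x̄(0))/C₀.

The decomposition φ = L ξ + x̄ is exact by construction. Its value is the
residual: under spatially uniform growth, ξ is frozen, so ξ-trajectories
isolate the *heterogeneous* part of morphogenesis and are comparable
between tissues of different size and staging scale. The ξ velocity obeys

    dξ/dt = L⁻¹ (S̄_X − S̄) L ξ − v_g,

with S̄ = (dF̄/dt) F̄⁻¹, S̄_X the analogous rate of the line-segment average
G(X, t) = ∫₀¹ F(εX, t) dε, and v_g a centroid-motion term. The line-segment
representation x = G(X, t) X requires a star-shaped domain and a material
point pinned at the origin; since a fitted map has no such point, all these
quantities are computed in the frame of the material point that starts at
the initial area centroid (positions are measured relative to that point's
trajectory). All identities quoted below hold in that frame.

Two species are compared by matching ξ-trajectory snapshots: the distance
δ(t_A, t_B) is the mean Euclidean ξ-distance over a fixed seed set Ω (the
overlap of both species' initial outlines in ξ-space, optionally restricted
to labeled prospective regions). Row/column argmins of the δ matrix define
the composite stage maps in both directions; where the underlying dynamics
agree these maps are monotone, continuous and mutually inverse, and a
linear stage correspondence can be fitted. Region-restricted comparison
re-derives the entire rescaling (C₀, F̄, L, x̄) on a candidate sub-region
parameterized by (α, β, θ) and reports η (the temporal mean of per-stage
minimal δ) together with CV_β[θ*], the coefficient of variation across the
β-grid of the η-minimizing axis angle — an overfitting indicator: small
regions can be made to match by tuning the axis, and that shows up as a
β-sensitive optimal angle.

## Estimators and numerical choices

**Per-interval map fit.** Landmark pairs of one stage interval are fitted
with an affine mean (ordinary least squares, exact on affine data) plus a
per-component Gaussian-process residual field with a shared isotropic RBF
kernel and white noise. Hyperparameters maximize the marginal likelihood;
because the likelihood surface has a spurious "all noise" optimum at very
large length scales, the optimizer is started from three log-spaced length
scales (diameter/16, /6, /2) and the best evidence wins. This smooth-field
regression is this package's own estimator, not a port of any published
implementation; typical mean residuals under the default synthetic
conditions are ~12 µm at σ = 10 µm measurement noise.

**Composition.** Interval maps chain exactly at interval boundaries;
within an interval, positions follow linear displacement interpolation
(mirroring how spot positions between measurements are interpolated).
Jacobians chain analytically. Inversion is Newton iteration from a
coarse-grid initialization (tolerance 1e-6 µm). Orientation is checked on
an evaluation grid; folds (det F ≤ 0) warn rather than fail, since noisy
fits may fold locally.

**Average growth of fitted maps.** For composite fitted maps, F̄(t) is
estimated by chaining the per-interval affine components (the data-weighted
spatial mean of each interval's gradient) rather than by quadrature of
pointwise Jacobians. Pointwise Jacobians of a smoothed field are biased
near the data boundary, and that bias compounds multiplicatively across
chained intervals; stage matching is extremely sensitive to the resulting
slow dilation of L(t) (a ~3% dilation drift mimics a large stage shift).
The affine-chain estimator is nearly unbiased and scale-equivariant, so the
residual bias largely cancels between species. Analytic maps (and the
`mean_deformation_gradient` helper) use area-weighted cell quadrature:
boundary grid cells are weighted by their clipped area, giving second-order
convergence under refinement.

**Derivatives in stage.** S̄, S̄_X and v_g use central differences on the
stage grid (one-sided at the ends, with a warning in the single-point
helper); the line-segment average uses 16-point Gauss–Legendre quadrature
by default (64 points in the star-domain diagnostic).

**Known limitation — strong rotational flows.** When material rotates
substantially along the ray from the origin to X, the line-segment average
G(X, t) can become nearly singular, and S̄_X (hence the ξ-velocity
evaluation, though not the ξ-trajectories themselves) is unreliable there;
`XiDynamics.velocity` warns when det G degenerates. The default synthetic
flow is strong enough to trigger this for a few peripheral seeds at late
stages; the velocity-equation verification therefore uses analytic test
maps within the formulation's domain of validity.

**Clock synchronization.** δ matrices are computed over each species' full
stage-grid product; argmin ties break toward the earlier stage. The valid
(homeomorphic) range is the largest initial segment on which both composite
maps are monotone with jumps bounded by the nominal increment plus one
grid step and are mutually inverse within one source step plus one target
step (the discretization floor of an argmin correspondence). For warp
recovery the slope is estimated symmetrically — the geometric mean of the
A→B fit and the reciprocal of the B→A fit — because the two directions'
biases largely cancel; the intercept is anchored at the grid center.

**Region comparison.** The candidate region is the distal α-fraction of
the chord cut by the (θ-rotated, β-offset) axis through the outline; the
chord construction (rather than a pure projection) is what makes the
region genuinely β-dependent, which the CV overfitting probe requires.
Restricted dynamics are recomputed from a cached field (positions and
gradients precomputed on a master lattice, restriction = masked averages
plus linear interpolation), which makes dense (α, β, θ) scans cheap.

**Bootstrap.** Replicates resample pairs with replacement per interval at
the original count and refit the full composite map (B = 150 by default).
The intraspecies variability envelope is mean ± 2.8 SD per coordinate
component across replicates — the Gaussian approximation of the min–max
spread of 150 replicates. Reduced-B runs keep this definition: the raw
min–max of B = 30 draws has an ideal bracketing probability of only
(B−1)/(B+1) per component, below any useful calibration target by
construction.

## The synthetic generator

The generator realizes the archetype hypothesis directly: one smooth cell
flow v(ξ, τ) in dimensionless ξ-space drives every species; each species
applies its own linear growth schedule F̄_s(τ) (with F̄_s(τ₀) = I), scale
c₀, centroid drift, and a linear stage warp t = aτ + b. A species' domain
is a polygon in archetype coordinates — the full reference bud, or a distal
sub-region for a species whose bud omits proximal tissue, which is how the
region-comparison scenario plants a conserved extent (default distal
fraction 0.7, cut along an axis rotated by 0.15 rad so the optimal angle
has a nonzero mean and the CV statistic is well defined).

The flow has two closed-form parts. The dominant term is a divergence-free
circulation from the streamfunction ψ = s·E(ξ)·B(ξ), where E is the bud
shape function (an asymmetric quadric whose unit level set *is* the
reference outline) and B a Gaussian bump over the posterior half. Because
the outline is a streamline, trajectories started inside stay inside
without any artificial slip layer at the boundary — important because a
flow forced to vanish on the outline concentrates its gradients exactly
where landmark data cannot constrain a fit, which would make every
mean-growth estimator boundary-biased. The second term is a small
compressible antero-posterior drift (damped by E) that makes local area
growth A-P asymmetric. Default strengths (circulation 0.11, drift 0.03 per
τ unit) give a mean rescaled speed of ~0.10/τ and total drifts up to ~1 ξ
unit over the nine-interval span, i.e. posterior cells sweep across a
large fraction of the bud — the regime the motivating observations
describe (the posterior part of the late autopod derives from a small
posterior portion of the early bud).

Defaults mirror the study conditions: a τ span of 9 units divided into 9
intervals; species A with c₀ = 400 µm and stages 50.6–54.2 (warp 0.4τ +
50.6), species B with c₀ = 800 µm (about twice the size per axis) and
stages 21–30 (warp τ + 21); measurement noise σ = 10 µm i.i.d. per
coordinate per measurement; 11 individuals with overlapping stage windows
whose per-interval spanning totals reproduce the configured pair counts
(113, 185, 67, 79, 226, 333, 256, 129, 270) exactly — nine single-interval
individuals plus two spanning individuals (intervals 2–4 and 6–8). Spot
seeds are gridded with jitter inside the initial domain and advected by
the true map; trajectories integrate with classical RK4 at a fixed step of
1/200 of the τ span, so oracle values are bit-reproducible given a seed.
Divergence scenarios switch on a species-specific smooth perturbation
field (amplitude 0.3 per τ unit) after an onset τ*.

What the generator does *not* emulate: measurement dropout and spot
mis-identification, stage-estimation error (stage values are exact),
curvature of the real stage warp (linear by default), out-of-plane (D-V)
motion, and biomechanics of any kind (flows are kinematic prescriptions).
Passing tests therefore certify the estimators and the comparison
machinery under honest noise and sampling, not robustness to staging error
or 3D artifacts.

## Problem sizes used in the shipped tests and reproduction script

Stage grids are refined 2–3 sub-steps per interval; seed lattices use
spacings 0.06–0.15 ξ units (a few hundred seeds); quadrature lattices about
30 cells across the bud; warp recovery averages two measurement replicates
per planted slope; the bootstrap calibration run uses B = 30. These sizes
keep the full suite and the reproduction script in the minutes range while
leaving every measured quantity's convergence verified by the refinement
tests alongside.
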