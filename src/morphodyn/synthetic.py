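"""Ground-truth two-species morphodynamic scenarios.

The generator realizes the archetype hypothesis directly: a single smooth
cell flow v(xi, tau) in dimensionless xi-space drives both species; each
species is a time-variant linear transformation of that common flow,

    phi_s(X, t) = c0_s * Fbar_s(tau) * xi(xi_arch, tau) + xbar_s(tau),
    t = a_s * tau + b_s  (species stage warp, linear by default),

where xi_arch = X / c0_s are archetype coordinates of the species' material
points, Fbar_s is a smooth growth schedule with Fbar_s(tau0) = I, and the
species' domain is a polygon in archetype coordinates (the full reference
bud, or a distal sub-region of it for a species whose bud omits proximal
tissue).  Trajectories are integrated by classical RK4 with a fixed step
(1/200 of the tau span), so oracle values are reproducible.

Noisy labeled-spot datasets emulate the measurement design: 11 individuals
with overlapping stage windows whose per-interval pair counts reproduce the
configured targets exactly, gridded-with-jitter spot seeding, and iid
Gaussian position noise (default sigma = 10 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from shapely.geometry import Polygon

from .datamodel import (SpotRecord, StageGrid, TissueOutline,
                        lattice_in_polygon)
from .rescaling import centroid_size, resample_ring

# default per-interval pair-count targets for the measurement design
DEFAULT_INTERVAL_COUNTS = (113, 185, 67, 79, 226, 333, 256, 129, 270)


# ---------------------------------------------------------------------------
# reference bud outline (archetype coordinates, centroid size 1)
# ---------------------------------------------------------------------------

# shape function whose unit level set is the reference bud outline; the
# archetype circulation uses it as a streamfunction envelope so the outline
# is a streamline (flow tangential at the boundary, no artificial slip layer)
_SHAPE_A, _SHAPE_B, _SHAPE_D = 1.25, 0.95, 0.30


def _shape_Q(x1, x2):
    return (x1 / _SHAPE_A) ** 2 + (x2 / _SHAPE_B) ** 2 \
        + _SHAPE_D * x1 * (x2 / _SHAPE_B) ** 2


def _shape_Q_grad(x1, x2):
    g1 = 2 * x1 / _SHAPE_A**2 + _SHAPE_D * (x2 / _SHAPE_B) ** 2
    g2 = 2 * x2 / _SHAPE_B**2 + 2 * _SHAPE_D * x1 * x2 / _SHAPE_B**2
    return g1, g2


def _raw_bud_ring(n: int = 256) -> np.ndarray:
    """Ring of the Q = 1 level set, solved radially (star-shaped)."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ct, st = np.cos(th), np.sin(th)
    r = np.empty(n)
    for i in range(n):
        lo, hi = 1e-6, 4.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _shape_Q(mid * ct[i], mid * st[i]) < 1.0:
                lo = mid
            else:
                hi = mid
        r[i] = 0.5 * (lo + hi)
    return np.column_stack([r * ct, r * st])


def _normalized_bud(n: int = 256) -> tuple[np.ndarray, float, np.ndarray]:
    """(ring, scale, offset) with the ring centered on its area centroid
    and normalized to centroid size 1; raw = scale * ring + offset."""
    raw = _raw_bud_ring(n)
    c = Polygon(raw).centroid
    offset = np.array([c.x, c.y])
    scale = centroid_size(raw - offset)
    return (raw - offset) / scale, scale, offset


def unit_bud_outline(n: int = 256) -> np.ndarray:
    """Smooth asymmetric limb-bud-like ring (centroid at the origin,
    centroid size 1).  Star-shaped about the origin."""
    return _normalized_bud(n)[0]


def clip_distal(vertices: np.ndarray, fraction: float,
                angle: float = 0.0) -> np.ndarray:
    """Distal-``fraction`` clip of a ring along a P-D axis rotated by
    ``angle`` (radians), as a new ring."""
    poly = Polygon(vertices)
    u = np.array([np.cos(angle), np.sin(angle)])
    w = np.array([-np.sin(angle), np.cos(angle)])
    s = vertices @ u
    cut = s.max() - fraction * (s.max() - s.min())
    span = 4.0 * max(np.abs(vertices).max(), 1.0)
    corners = [cut * u - span * w, (cut + span) * u - span * w,
               (cut + span) * u + span * w, cut * u + span * w]
    clipped = poly.intersection(Polygon(corners))
    return resample_ring(np.asarray(clipped.exterior.coords)[:-1], 200)


# ---------------------------------------------------------------------------
# archetype flow
# ---------------------------------------------------------------------------

@dataclass
class ArchetypeFlow:
    """Smooth species-shared velocity field v(xi, tau) in xi-space.

    Two closed-form components:

    * ``ap_asymmetry`` scales a divergence-free circulation built from the
      streamfunction psi = E(xi) * B(xi), where E is the bud shape function
      (zero on the reference outline, so the outline is a streamline and
      trajectories started inside remain inside) and B is a Gaussian bump
      centered on the posterior half.  The resulting cell flow sweeps
      posterior cells toward the anterior through the bud interior — the
      dominant rescaled motion the comparison is built to detect.
    * ``growth_asymmetry`` scales a small compressible A-P drift toward
      ``ap_center`` (damped by E so the boundary stays invariant), which
      makes the local area growth antero-posteriorly asymmetric.

    All strengths zero gives v == 0.
    """

    ap_asymmetry: float = 0.11        # circulation strength per tau unit
    growth_asymmetry: float = 0.03    # compressible drift per tau unit
    ap_center: float = 0.25           # A-P coordinate the drift converges to
    bump_center: tuple[float, float] = (0.15, -0.35)
    bump_width: float = 0.55
    seed: int = 0
    outline: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.ap_asymmetry < 0 or self.growth_asymmetry < 0:
            raise ValueError("flow strengths must be >= 0")
        self.outline, self._scale, self._offset = _normalized_bud()

    def _E(self, xi: np.ndarray) -> np.ndarray:
        p = self._scale * xi + self._offset
        return 1.0 - _shape_Q(p[:, 0], p[:, 1])

    def _E_grad(self, xi: np.ndarray) -> np.ndarray:
        p = self._scale * xi + self._offset
        g1, g2 = _shape_Q_grad(p[:, 0], p[:, 1])
        return -self._scale * np.column_stack([g1, g2])

    def envelope(self, xi: np.ndarray) -> np.ndarray:
        """Shape envelope, 1-ish in the center, 0 on the outline."""
        return np.clip(self._E(np.atleast_2d(xi)), 0.0, None)

    def __call__(self, xi: np.ndarray, tau: float) -> np.ndarray:
        xi = np.atleast_2d(np.asarray(xi, dtype=float))
        E = self._E(xi)
        dE = self._E_grad(xi)
        d = xi - np.asarray(self.bump_center)
        B = np.exp(-np.sum(d**2, axis=1) / (2 * self.bump_width**2))
        dB = -(B[:, None] / self.bump_width**2) * d
        # psi = s * E * B ; v = (dpsi/dxi2, -dpsi/dxi1)
        dpsi = self.ap_asymmetry * (B[:, None] * dE + E[:, None] * dB)
        v = np.column_stack([dpsi[:, 1], -dpsi[:, 0]])
        v[:, 1] += self.growth_asymmetry * np.clip(E, 0, None) * (self.ap_center - xi[:, 1])
        return v


def make_archetype_flow(params: dict | None = None, seed: int = 0) -> ArchetypeFlow:
    """Build the default archetype flow, optionally overriding parameters."""
    return ArchetypeFlow(seed=seed, **(params or {}))


def divergence_field(seed: int = 0) -> Callable[[np.ndarray], np.ndarray]:
    """A smooth species-specific perturbation field (unit amplitude),
    deterministic given seed; used after a divergence onset."""
    rng = np.random.default_rng(seed)
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    k1, k2 = rng.uniform(1.5, 3.0, 2)

    def u(xi: np.ndarray) -> np.ndarray:
        xi = np.atleast_2d(xi)
        return np.column_stack([np.sin(k1 * xi[:, 1] + p1), np.cos(k2 * xi[:, 0] + p2)])

    return u


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """Species-specific factors applied to the common flow."""

    name: str
    c0_scale: float = 400.0            # um per archetype xi unit
    growth_pd: float = 0.22            # Fbar_11 rate per tau unit
    growth_ap: float = 0.12
    shear: float = 0.0
    centroid_velocity: tuple[float, float] = (6.0, 2.0)   # um per tau unit
    warp_a: float = 1.0                # t = warp_a * tau + warp_b
    warp_b: float = 0.0
    tau0: float = 0.0
    tau1: float = 9.0
    n_intervals: int = 9
    outline_arch: np.ndarray = field(default_factory=unit_bud_outline)
    region_fractions: dict = field(
        default_factory=lambda: {"autopod": (0.0, 0.4), "zeugopod": (0.4, 0.7)})
    divergence_onset: float | None = None      # tau* after which species deviates
    divergence_strength: float = 0.0           # xi units per tau, after onset
    divergence_seed: int = 0

    def __post_init__(self):
        if self.warp_a <= 0:
            raise ValueError("stage warp must be strictly increasing")
        if self.growth_pd <= -1 / (self.tau1 - self.tau0) or \
           self.growth_ap <= -1 / (self.tau1 - self.tau0):
            raise ValueError("growth schedule would make det L <= 0")

    def Fbar(self, tau: float) -> np.ndarray:
        d = tau - self.tau0
        return np.array([[1 + self.growth_pd * d, self.shear * d],
                         [0.0, 1 + self.growth_ap * d]])

    def centroid_path(self, tau: float) -> np.ndarray:
        return np.asarray(self.centroid_velocity) * (tau - self.tau0)

    def stage_of(self, tau):
        return self.warp_a * np.asarray(tau) + self.warp_b

    def tau_of(self, t):
        return (np.asarray(t) - self.warp_b) / self.warp_a


class GroundTruthMap:
    """Analytic species deformation map built from a shared xi-flow.

    Implements the same protocol as a fitted composite map: ``trajectory``,
    ``gradient_trajectory`` (central finite differences on trajectories,
    step 1e-3 of the domain diameter), ``__call__``, ``invert`` via the
    shared Newton helper, plus ``outline_at`` for advected outlines.
    """

    N_STEPS = 200   # RK4 steps across the full tau span

    def __init__(self, flow: ArchetypeFlow, spec: SpeciesSpec):
        self.flow = flow
        self.spec = spec
        endpoints = spec.stage_of(np.linspace(spec.tau0, spec.tau1, spec.n_intervals + 1))
        self.stage_grid = StageGrid(spec.name, endpoints)
        verts = spec.c0_scale * np.asarray(spec.outline_arch)
        regions = {}
        s = np.asarray(spec.outline_arch)[:, 0]
        for name, (f0, f1) in spec.region_fractions.items():
            ring = self._band_clip(np.asarray(spec.outline_arch), f0, f1)
            regions[name] = Polygon(spec.c0_scale * ring)
        self.initial_domain = TissueOutline(float(endpoints[0]), Polygon(verts), regions)
        if spec.divergence_onset is not None:
            self._pert = divergence_field(spec.divergence_seed)
        else:
            self._pert = None

    @staticmethod
    def _band_clip(arch: np.ndarray, f0: float, f1: float) -> np.ndarray:
        s = arch[:, 0]
        smax, smin = s.max(), s.min()
        hi_cut = smax - f0 * (smax - smin)
        lo_cut = smax - f1 * (smax - smin)
        poly = Polygon(arch)
        lo, hi = poly.bounds[1] - 1, poly.bounds[3] + 1
        band = Polygon([(lo_cut, lo), (hi_cut, lo), (hi_cut, hi), (lo_cut, hi)])
        sub = poly.intersection(band)
        return resample_ring(np.asarray(sub.exterior.coords)[:-1], 120)

    # -- velocity including any species-specific divergence term ------------
    def _v(self, xi: np.ndarray, tau: float) -> np.ndarray:
        v = self.flow(xi, tau)
        if self._pert is not None and tau > self.spec.divergence_onset:
            amp = self.spec.divergence_strength
            v = v + amp * self.flow.envelope(np.atleast_2d(xi))[:, None] * self._pert(xi)
        return v

    def xi_trajectory(self, xi0: np.ndarray, taus: Sequence[float]) -> np.ndarray:
        """Integrate the flow from xi0 (n,2) recording at each tau, (n,T,2)."""
        xi0 = np.atleast_2d(np.asarray(xi0, dtype=float))
        taus = np.asarray(taus, dtype=float)
        out = np.empty((len(xi0), len(taus), 2))
        xi = xi0.copy()
        tau = self.spec.tau0
        base = (self.spec.tau1 - self.spec.tau0) / self.N_STEPS
        for j, taut in enumerate(taus):
            dt = taut - tau
            if dt > 1e-12:
                nsub = max(1, int(np.ceil(dt / base - 1e-9)))
                h = dt / nsub
                for _ in range(nsub):
                    k1 = self._v(xi, tau)
                    k2 = self._v(xi + 0.5 * h * k1, tau + 0.5 * h)
                    k3 = self._v(xi + 0.5 * h * k2, tau + 0.5 * h)
                    k4 = self._v(xi + h * k3, tau + h)
                    xi = xi + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
                    tau += h
                tau = taut
            out[:, j] = xi
        return out

    # -- map protocol --------------------------------------------------------
    @property
    def t0(self) -> float:
        return float(self.stage_grid.stages[0])

    def trajectory(self, X: np.ndarray, stages: Sequence[float]) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        stages = np.asarray(stages, dtype=float)
        taus = self.spec.tau_of(stages)
        xi = self.xi_trajectory(X / self.spec.c0_scale, taus)
        out = np.empty_like(xi)
        for j, tau in enumerate(taus):
            L = self.spec.c0_scale * self.spec.Fbar(tau)
            out[:, j] = xi[:, j] @ L.T + self.spec.centroid_path(tau)
        return out

    def __call__(self, X: np.ndarray, t: float) -> np.ndarray:
        return self.trajectory(X, [t])[:, 0]

    def gradient_trajectory(self, X: np.ndarray, stages: Sequence[float]
                            ) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        stages = np.asarray(stages, dtype=float)
        diam = 2 * self.spec.c0_scale * float(np.abs(self.spec.outline_arch).max())
        h = 1e-3 * diam
        pos = self.trajectory(X, stages)
        n = len(X)
        shifts = np.array([[h, 0], [-h, 0], [0, h], [0, -h]])
        stacked = (X[None, :, :] + shifts[:, None, :]).reshape(-1, 2)
        p = self.trajectory(stacked, stages).reshape(4, n, len(stages), 2)
        F = np.empty((n, len(stages), 2, 2))
        F[..., 0] = (p[0] - p[1]) / (2 * h)    # d phi / d X1
        F[..., 1] = (p[2] - p[3]) / (2 * h)    # d phi / d X2
        return pos, F

    def gradient(self, X: np.ndarray, t: float) -> np.ndarray:
        return self.gradient_trajectory(X, [t])[1][:, 0]

    def outline_at(self, t: float) -> TissueOutline:
        v = self.trajectory(self.initial_domain.vertices, [t])[:, 0]
        regions = {k: Polygon(self.trajectory(np.asarray(p.exterior.coords)[:-1], [t])[:, 0])
                   for k, p in self.initial_domain.regions.items()}
        return TissueOutline(float(t), Polygon(v), regions)


def make_species(flow: ArchetypeFlow, spec: SpeciesSpec) -> GroundTruthMap:
    return GroundTruthMap(flow, spec)


# ---------------------------------------------------------------------------
# measurement design and spot sampling
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    """One measured individual: which grid intervals its window spans and
    how many spots it carries."""

    individual_id: str
    first_interval: int   # 0-based, inclusive
    last_interval: int    # inclusive
    n_spots: int


@dataclass
class MeasurementDesign:
    individuals: list[Individual]
    noise_sigma: float = 10.0   # um
    seed: int = 0

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def default_design(counts: Sequence[int] = DEFAULT_INTERVAL_COUNTS,
                   noise_sigma: float = 10.0, seed: int = 0) -> MeasurementDesign:
    """11 individuals with overlapping windows whose per-interval spanning
    totals reproduce ``counts`` exactly: nine single-interval individuals
    plus two spanning individuals (intervals 2-4 and 6-8, 1-based)."""
    counts = list(counts)
    if len(counts) != 9:
        raise ValueError("default design expects 9 interval counts")
    m10, m11 = 30, 40
    singles = list(counts)
    for k in (1, 2, 3):
        singles[k] -= m10
    for k in (5, 6, 7):
        singles[k] -= m11
    if min(singles) <= 0:
        raise ValueError("interval counts too small for the overlap allocation")
    inds = [Individual(f"ind{k + 1:02d}", k, k, singles[k]) for k in range(9)]
    inds.append(Individual("ind10", 1, 3, m10))
    inds.append(Individual("ind11", 5, 7, m11))
    return MeasurementDesign(inds, noise_sigma=noise_sigma, seed=seed)


def uniform_design(n_per_interval: int = 150, n_intervals: int = 9,
                   noise_sigma: float = 10.0, seed: int = 0) -> MeasurementDesign:
    """One individual per interval, ``n_per_interval`` spots each."""
    inds = [Individual(f"ind{k + 1:02d}", k, k, n_per_interval)
            for k in range(n_intervals)]
    return MeasurementDesign(inds, noise_sigma=noise_sigma, seed=seed)


def _jittered_lattice(polygon: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Roughly gridded points with jitter inside a polygon, exactly n of them."""
    import shapely
    spacing = float(np.sqrt(polygon.area / max(n, 1)))
    for _ in range(40):
        pts = lattice_in_polygon(polygon, spacing)
        if len(pts) >= n:
            jittered = pts + rng.uniform(-0.3 * spacing, 0.3 * spacing, size=pts.shape)
            inside = shapely.contains_xy(polygon, jittered[:, 0], jittered[:, 1])
            jittered = np.where(inside[:, None], jittered, pts)  # keep jitter inside
            keep = rng.permutation(len(jittered))[:n]
            if len(keep) >= n:
                return jittered[keep]
        spacing *= 0.92
    raise RuntimeError("could not place requested number of spots")

def sample_spots(gt_map: GroundTruthMap, design: MeasurementDesign) -> list[SpotRecord]:
    """Simulate the labeling experiment: per individual, material seeds are
    placed grid-with-jitter in the initial domain, advected by the true map
    to the individual's measurement stages (its window's grid endpoints),
    and recorded with iid Gaussian noise.  Bit-reproducible given the seed."""
    rng = np.random.default_rng(design.seed)
    stages = gt_map.stage_grid.stages
    records: list[SpotRecord] = []
    for ind in design.individuals:
        seeds = _jittered_lattice(gt_map.initial_domain.polygon, ind.n_spots, rng)
        meas_stages = stages[ind.first_interval: ind.last_interval + 2]
        true_pos = gt_map.trajectory(seeds, meas_stages)
        noisy = true_pos + rng.normal(0.0, design.noise_sigma, size=true_pos.shape) \
            if design.noise_sigma > 0 else true_pos
        for s_idx, t in enumerate(meas_stages):
            for j in range(ind.n_spots):
                records.append(SpotRecord(ind.individual_id, float(t),
                                          f"s{j + 1:04d}",
                                          (float(noisy[j, s_idx, 0]),
                                           float(noisy[j, s_idx, 1]))))
    return records


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

def species_A_spec(**over) -> SpeciesSpec:
    """Smaller, faster-staged species (bud about half the size per axis)."""
    kw = dict(name="speciesA", c0_scale=400.0, growth_pd=0.22, growth_ap=0.12,
              centroid_velocity=(6.0, 2.0), warp_a=0.4, warp_b=50.6)
    kw.update(over)
    return SpeciesSpec(**kw)


def species_B_spec(**over) -> SpeciesSpec:
    """Larger species with its own growth schedule and stage scale."""
    kw = dict(name="speciesB", c0_scale=800.0, growth_pd=0.20, growth_ap=0.11,
              shear=0.02, centroid_velocity=(10.0, 3.0), warp_a=1.0, warp_b=21.0)
    kw.update(over)
    return SpeciesSpec(**kw)


def two_species_scenario(seed: int = 0, warp_B: tuple[float, float] | None = None,
                         divergence_onset: float | None = None,
                         divergence_strength: float = 0.3,
                         ) -> tuple[ArchetypeFlow, GroundTruthMap, GroundTruthMap]:
    """Two full-bud species driven by one archetype flow; optionally give
    species B a different linear stage warp and/or a post-onset divergence."""
    flow = make_archetype_flow(seed=seed)
    spec_A = species_A_spec()
    over = {}
    if warp_B is not None:
        over = {"warp_a": warp_B[0], "warp_b": warp_B[1]}
    spec_B = species_B_spec(**over)
    if divergence_onset is not None:
        spec_B = replace(spec_B, divergence_onset=divergence_onset,
                         divergence_strength=divergence_strength,
                         divergence_seed=seed + 1)
    return flow, GroundTruthMap(flow, spec_A), GroundTruthMap(flow, spec_B)


def region_scenario(seed: int = 0, alpha_true: float = 0.7,
                    theta_true: float = 0.15
                    ) -> tuple[GroundTruthMap, GroundTruthMap]:
    """Species X carries the full bud; species C's bud is only the distal
    ``alpha_true`` fraction of the archetype domain (clipped along a P-D
    axis rotated by ``theta_true``), i.e. it omits proximal tissue.  The
    rescaled dynamics of the two species agree exactly when X is restricted
    to that same distal fraction and axis, and disagree otherwise."""
    flow = make_archetype_flow(seed=seed)
    spec_X = species_A_spec(name="speciesX")
    arch = unit_bud_outline()
    distal = clip_distal(arch, alpha_true, theta_true)
    spec_C = species_B_spec(
        name="speciesC", outline_arch=distal,
        region_fractions={"autopod": (0.0, min(1.0, 0.4 / alpha_true))})
    return GroundTruthMap(flow, spec_X), GroundTruthMap(flow, spec_C)


def refine_stage_grid(grid: StageGrid, factor: int = 4) -> np.ndarray:
    """Stage values subdividing each grid interval ``factor`` times."""
    s = grid.stages
    out = [np.linspace(s[i], s[i + 1], factor, endpoint=False) for i in range(len(s) - 1)]
    return np.concatenate(out + [s[-1:]])
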