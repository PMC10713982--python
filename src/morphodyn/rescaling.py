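"""Decomposition of tissue deformation into average growth and rescaled
(xi-space) dynamics.

The deformation map phi(X, t) of a growing tissue is factored as

    phi(X, t) = L(t) xi(xi0, t) + xbar(t),

where L(t) = C0 * Fbar(t) is the "multi-dimensional tissue size" (initial
centroid size C0 times the domain-averaged deformation gradient), xbar(t) is
the area centroid of the deformed domain, and xi(xi0, t) is the rescaled
cell position.  xi trajectories are what remains of the dynamics after
average growth and translation are cancelled: under spatially uniform
growth every xi trajectory is constant.

The xi velocity field obeys

    d xi / dt = L^-1 (S_X - S) L xi - v_g,

with S = (dFbar/dt) Fbar^-1 the global average velocity-gradient tensor,
S_X its line-segment average from the origin to the focal cell (defined
through the star-domain representation x = (int_0^1 F(eps X, t) d eps) X),
and v_g the contribution of centroid motion.  The origin of that
representation must be a material point pinned at 0; here all such
quantities are computed in the frame of the material point that starts at
the initial area centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import LinearNDInterpolator
from scipy.linalg import polar
from shapely.geometry import Polygon

from .datamodel import TissueOutline, lattice_in_polygon

__all__ = [
    "centroid_size", "resample_ring", "mean_deformation_gradient",
    "MeanGrowth", "XiDynamics", "decompose", "star_domain_residual",
    "pseudo_map", "ScalingOperator", "interspecies_scaling",
    "transform_points_to_xi", "FieldCache",
]


def resample_ring(vertices: np.ndarray, M: int = 200) -> np.ndarray:
    """Resample a closed vertex ring at M equally arc-length-spaced points."""
    v = np.asarray(vertices, dtype=float)
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate outline with zero perimeter")
    si = np.linspace(0.0, total, M, endpoint=False)
    out = np.empty((M, 2))
    out[:, 0] = np.interp(si, s, closed[:, 0])
    out[:, 1] = np.interp(si, s, closed[:, 1])
    return out


def centroid_size(outline: "TissueOutline | Polygon | np.ndarray", M: int = 200) -> float:
    """Centroid size of an outline: sqrt(sum |p_i - pbar|^2 / M) over M
    equally arc-length-spaced boundary samples.

    Dividing by sqrt(M) makes the value invariant to the sampling density;
    the same normalization is used when forming xi0 = X / C0, so the
    convention is self-consistent.
    """
    if isinstance(outline, TissueOutline):
        v = outline.vertices
    elif isinstance(outline, Polygon):
        v = np.asarray(outline.exterior.coords)[:-1]
    else:
        v = np.asarray(outline, dtype=float)
    p = resample_ring(v, M)
    p = p - p.mean(axis=0)
    c0 = float(np.sqrt(np.sum(p**2) / M))
    if c0 <= 0:
        raise ValueError("degenerate outline: zero centroid size")
    return c0


def _default_spacing(polygon: Polygon, n_across: int = 32) -> float:
    minx, miny, maxx, maxy = polygon.bounds
    return max(maxx - minx, maxy - miny) / n_across


def _cell_quadrature(polygon: Polygon, spacing: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centered quadrature with boundary cells weighted by their
    clipped area (second-order accurate despite the ragged boundary)."""
    from shapely.geometry import box
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.arange(minx, maxx + spacing, spacing)
    ys = np.arange(miny, maxy + spacing, spacing)
    pts, wts = [], []
    for x0 in xs:
        for y0 in ys:
            cell = box(x0, y0, x0 + spacing, y0 + spacing)
            inter = polygon.intersection(cell)
            if inter.is_empty or inter.area <= 0:
                continue
            c = inter.centroid
            pts.append([c.x, c.y])
            wts.append(inter.area)
    if not pts:
        raise ValueError("quadrature grid empty; decrease spacing")
    return np.asarray(pts), np.asarray(wts)


def mean_deformation_gradient(dmap, outline: TissueOutline, t: float,
                              spacing: float | None = None) -> np.ndarray:
    """Area-weighted spatial average Fbar(t) of the deformation gradient
    over the initial domain (cell quadrature clipped to the outline)."""
    spacing = spacing or _default_spacing(outline.polygon)
    pts, w = _cell_quadrature(outline.polygon, spacing)
    _, F = dmap.gradient_trajectory(pts, [t])
    return np.einsum("n,nij->ij", w, F[:, 0]) / w.sum()


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _interp_array(stages: np.ndarray, arr: np.ndarray, t: float) -> np.ndarray:
    """Linear interpolation of an array indexed by stage along axis 0."""
    t = float(t)
    if t <= stages[0]:
        return arr[0]
    if t >= stages[-1]:
        return arr[-1]
    k = int(np.searchsorted(stages, t)) - 1
    w = (t - stages[k]) / (stages[k + 1] - stages[k])
    return (1 - w) * arr[k] + w * arr[k + 1]


@dataclass
class MeanGrowth:
    """Average-growth factor of a deformation map.

    Fields are tabulated on the stage grid; ``*_at`` accessors interpolate
    linearly in stage.  L(t) = C0 * Fbar(t); centroid is the area centroid
    of the deformed domain, with xbar0 its value at the initial stage.
    """

    stages: np.ndarray
    C0: float
    Fbar: np.ndarray      # (nt, 2, 2)
    centroid: np.ndarray  # (nt, 2), um
    estimator: str = "quadrature"   # which Fbar route produced this growth
    Sbar: np.ndarray = field(init=False)

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=float)
        dF = np.gradient(self.Fbar, self.stages, axis=0)
        self.Sbar = dF @ np.linalg.inv(self.Fbar)

    @property
    def L(self) -> np.ndarray:
        return self.C0 * self.Fbar

    @property
    def xbar0(self) -> np.ndarray:
        return self.centroid[0]

    def L_at(self, t: float) -> np.ndarray:
        return self.C0 * _interp_array(self.stages, self.Fbar, t)

    def centroid_at(self, t: float) -> np.ndarray:
        return _interp_array(self.stages, self.centroid, t)

    def Sbar_at(self, t: float) -> np.ndarray:
        return _interp_array(self.stages, self.Sbar, t)

    def xi0_of(self, X: np.ndarray) -> np.ndarray:
        """Initial rescaled coordinate xi0 = (X - xbar0) / C0."""
        return (np.atleast_2d(np.asarray(X, float)) - self.xbar0) / self.C0

    def X_of_xi0(self, xi0: np.ndarray) -> np.ndarray:
        return self.xbar0 + self.C0 * np.atleast_2d(np.asarray(xi0, float))

    def xi_outline(self, outline: TissueOutline) -> Polygon:
        """The outline's image in xi space at the initial stage."""
        return Polygon(self.xi0_of(outline.vertices))


class XiDynamics:
    """Rescaled (xi-space) trajectories of a deformation map on a seed grid.

    ``positions`` is a callable (X, stages) -> (n, T, 2) giving physical
    trajectories of material points; by default the deformation map itself.
    """

    def __init__(self, dmap, growth: MeanGrowth, outline: TissueOutline,
                 seeds: np.ndarray, positions: Callable | None = None):
        self.map = dmap
        self.growth = growth
        self.outline = outline
        self.seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
        self._positions = positions or (lambda X, stages: dmap.trajectory(X, stages))
        self.xi = self.trajectories(self.seeds)

    @property
    def stages(self) -> np.ndarray:
        return self.growth.stages

    @property
    def xi_outline(self) -> Polygon:
        return self.growth.xi_outline(self.outline)

    def xi_of_X(self, X: np.ndarray) -> np.ndarray:
        """xi trajectories (n, nt, 2) of physical material points X."""
        stages = self.growth.stages
        pos = self._positions(np.atleast_2d(np.asarray(X, float)), stages)
        Linv = np.linalg.inv(self.growth.L)                 # (nt, 2, 2)
        rel = pos - self.growth.centroid[None, :, :]
        return np.einsum("tij,ntj->nti", Linv, rel)

    def trajectories(self, seeds: np.ndarray) -> np.ndarray:
        """xi trajectories (n, nt, 2) for seeds given as xi0 coordinates."""
        return self.xi_of_X(self.growth.X_of_xi0(seeds))

    def at_stage(self, seeds: np.ndarray, t: float) -> np.ndarray:
        """xi positions of the given seeds at stage t (linear in stage)."""
        xi = self.trajectories(seeds)
        return _interp_array(self.growth.stages, np.moveaxis(xi, 1, 0), t)

    # -- velocity field (Eq. of motion in xi space) -------------------------
    def velocity(self, seeds: np.ndarray | None = None, include_vg: bool = True,
                 n_eps: int = 16) -> np.ndarray:
        """xi-velocity d xi / dt on the stage grid, shape (n, nt, 2).

        Evaluates L^-1 (S_X - S) L xi - v_g with S_X from the line-segment
        average of F (Gauss-Legendre with ``n_eps`` nodes) and time
        derivatives by central differences on the stage grid (one-sided at
        the grid ends).  ``include_vg=False`` drops the centroid-motion term
        (the small-centroid-motion approximation).
        """
        g = self.growth
        seeds = self.seeds if seeds is None else np.atleast_2d(np.asarray(seeds, float))
        stages = g.stages
        X = g.X_of_xi0(seeds)                                # (n, 2)
        n = len(X)

        # line-segment average G(X, t) = int_0^1 F(origin + eps*(X-origin)) d eps
        nodes, wts = leggauss(n_eps)
        eps = 0.5 * (nodes + 1.0)
        w = 0.5 * wts
        origin = g.xbar0
        P = origin + eps[None, :, None] * (X - origin)[:, None, :]   # (n, q, 2)
        _, F = self.map.gradient_trajectory(P.reshape(-1, 2), stages)
        F = F.reshape(n, n_eps, len(stages), 2, 2)
        G = np.einsum("q,nqtij->ntij", w, F)                 # (n, nt, 2, 2)
        detG = np.linalg.det(G)
        if np.min(np.abs(detG)) < 1e-3 * np.median(np.abs(detG)):
            warnings.warn(
                "line-segment average G(X, t) is nearly singular for some "
                "seeds; the xi-velocity decomposition is unreliable there "
                "(large rotational deformation along the ray)")
        dG = np.gradient(G, stages, axis=1)
        S_X = dG @ np.linalg.inv(G)                          # (n, nt, 2, 2)

        xi = self.trajectories(seeds)                        # (n, nt, 2)
        L = g.L                                              # (nt, 2, 2)
        Linv = np.linalg.inv(L)
        A = np.einsum("tij,ntjk,tkl->ntil", Linv, S_X - g.Sbar[None], L)
        v = np.einsum("ntij,ntj->nti", A, xi)
        if include_vg:
            # centroid path in the pinned-origin frame
            c_mat = self._positions(origin[None, :], stages)[0]      # (nt, 2)
            xbar_rel = g.centroid - c_mat
            dxbar = np.gradient(xbar_rel, stages, axis=0)
            vg_raw = dxbar[None] - np.einsum("ntij,tj->nti", S_X, xbar_rel)
            v_g = np.einsum("tij,ntj->nti", Linv, vg_raw)
            v = v - v_g
        return v

    def xi_velocity(self, xi0: np.ndarray, t: float, include_vg: bool = True) -> np.ndarray:
        """xi velocity of a single seed at stage t (interpolated in stage)."""
        stages = self.growth.stages
        if np.isclose(t, stages[0]) or np.isclose(t, stages[-1]):
            warnings.warn("stage at grid boundary: one-sided time difference used")
        v = self.velocity(np.atleast_2d(xi0), include_vg=include_vg)
        return _interp_array(stages, np.moveaxis(v, 1, 0), t)[0]


def _affine_chain_Fbar(dmap, stages: np.ndarray) -> np.ndarray:
    """Mean deformation gradient of a composite fitted map estimated from
    the chained per-interval affine components (the data-weighted spatial
    mean of each interval's gradient field).

    Unlike pointwise-Jacobian quadrature this is insensitive to smoothing
    bias of the residual field near the data boundary, which otherwise
    accumulates multiplicatively across chained intervals.
    """
    chain = [np.eye(2)]
    for m in dmap.interval_maps:
        chain.append(m.A @ chain[-1])
    out = []
    for t in stages:
        k, frac = dmap._locate(t)
        J = (1 - frac) * np.eye(2) + frac * dmap.interval_maps[k].A
        out.append(J @ chain[k])
    return np.asarray(out)


def decompose(dmap, outline: TissueOutline | None = None,
              stages: Sequence[float] | None = None,
              quad_spacing: float | None = None,
              seed_spacing: float = 0.02,
              growth_estimator: str = "auto") -> tuple[MeanGrowth, XiDynamics]:
    """Factor a deformation map into average growth and xi-space dynamics.

    Fbar(t) is the spatial mean of F over the initial outline; the centroid
    path is the det-F-weighted (area-element) mean of deformed positions;
    seeds for the xi trajectories form a regular lattice in xi0 clipped to
    the outline (default spacing 0.02 dimensionless units).  By
    construction L(t) xi + xbar(t) reproduces phi to round-off.

    ``growth_estimator``: "quadrature" averages pointwise Jacobians on a
    lattice; "affine_chain" (composite fitted maps only) chains the
    per-interval affine components; "auto" picks affine_chain for fitted
    composites and quadrature otherwise.
    """
    outline = outline or dmap.initial_domain
    if outline is None:
        raise ValueError("an initial outline is required")
    stages = np.asarray(stages if stages is not None else dmap.stage_grid.stages, float)
    spacing = quad_spacing or _default_spacing(outline.polygon)
    pts, w = _cell_quadrature(outline.polygon, spacing)
    pos, F = dmap.gradient_trajectory(pts, stages)
    if growth_estimator == "auto":
        growth_estimator = ("affine_chain" if getattr(dmap, "interval_maps", None)
                            else "quadrature")
    if growth_estimator == "affine_chain":
        Fbar = _affine_chain_Fbar(dmap, stages)
    else:
        Fbar = np.einsum("n,ntij->tij", w, F) / w.sum()      # (nt, 2, 2)
    if np.min(np.linalg.det(Fbar)) <= 0:
        raise ValueError("singular average growth tensor L(t)")
    detF = w[:, None] * np.linalg.det(F)                     # area weights (nq, nt)
    wsum = detF.sum(axis=0)
    centroid = np.einsum("nt,nti->ti", detF, pos) / wsum[:, None]
    C0 = centroid_size(outline)
    growth = MeanGrowth(stages, C0, Fbar, centroid, estimator=growth_estimator)
    xi_poly = growth.xi_outline(outline)
    seeds = lattice_in_polygon(xi_poly, seed_spacing)
    return growth, XiDynamics(dmap, growth, outline, seeds)


# ---------------------------------------------------------------------------
# star-domain representation
# ---------------------------------------------------------------------------

def star_domain_residual(dmap, X: np.ndarray, t: float,
                         origin: np.ndarray | None = None,
                         n_quad: int = 64) -> np.ndarray:
    """Residual of the line-integral map representation
    |x(X,t) - (int_0^1 F(eps X, t) d eps) X| in the pinned-origin frame.

    ``origin`` defaults to the area centroid of the map's initial domain.
    The segment origin->X must stay inside the domain (star-shaped about
    the origin); exits raise a ValueError.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if origin is None:
        if dmap.initial_domain is None:
            raise ValueError("origin required when the map has no initial domain")
        c = dmap.initial_domain.polygon.centroid
        origin = np.array([c.x, c.y])
    poly = dmap.initial_domain.polygon if dmap.initial_domain is not None else None
    nodes, wts = leggauss(n_quad)
    eps = 0.5 * (nodes + 1.0)
    w = 0.5 * wts
    if poly is not None:
        import shapely
        seg = origin + eps[None, :, None] * (X - origin)[:, None, :]
        buffered = poly.buffer(1e-9 * max(poly.bounds[2] - poly.bounds[0], 1.0))
        inside = shapely.contains_xy(buffered, seg[..., 0].ravel(), seg[..., 1].ravel())
        if not np.all(inside):
            raise ValueError("segment from origin exits the domain (not star-shaped here)")
    P = origin + eps[None, :, None] * (X - origin)[:, None, :]
    _, F = dmap.gradient_trajectory(P.reshape(-1, 2), [t])
    G = np.einsum("q,nqij->nij", w, F.reshape(len(X), n_quad, 2, 2))
    pred = np.einsum("nij,nj->ni", G, X - origin)
    x_rel = dmap(X, t) - dmap(origin[None, :], t)[0]
    return np.linalg.norm(x_rel - pred, axis=1)


# ---------------------------------------------------------------------------
# cross-species operators
# ---------------------------------------------------------------------------

def pseudo_map(growth_A: MeanGrowth, dyn_B: XiDynamics, seeds: np.ndarray,
               t_A: float, t_B: float) -> np.ndarray:
    """Pseudo deformation map: species-A average growth applied to
    species-B rescaled positions,  L_A(t_A) xi_B(xi0, t_B) + xbar_A(t_A).

    With A = B and t_A = t_B this reproduces the true map exactly.  Seeds
    outside B's domain yield NaN rows (per-seed missing-value flag).
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    import shapely
    inside = shapely.contains_xy(dyn_B.xi_outline.buffer(1e-9),
                                 seeds[:, 0], seeds[:, 1])
    xi_B = dyn_B.at_stage(seeds, t_B)
    L = growth_A.L_at(t_A)
    out = xi_B @ L.T + growth_A.centroid_at(t_A)
    out[~inside] = np.nan
    return out


@dataclass
class ScalingOperator:
    """Time-variant linear transformation mapping one species' mean growth
    onto another's: M = L_A L_B^-1 = R U (rotation times right stretch)."""

    M: np.ndarray
    R: np.ndarray
    U: np.ndarray
    stretches: np.ndarray       # eigenvalues of U, descending
    axes: np.ndarray            # corresponding eigenvectors (columns)


def interspecies_scaling(growth_A: MeanGrowth, growth_B: MeanGrowth,
                         t_A: float, t_B: float | None = None) -> ScalingOperator:
    """Scaling operator M = L_A(t_A) L_B(t_B)^-1 with polar decomposition
    M = R U; the eigen-axes of U are the principal scaling directions."""
    t_B = t_A if t_B is None else t_B
    L_B = growth_B.L_at(t_B)
    if abs(np.linalg.det(L_B)) < 1e-300:
        raise ValueError("singular L_B")
    M = growth_A.L_at(t_A) @ np.linalg.inv(L_B)
    R, U = polar(M, side="right")     # M = R U, U symmetric positive-definite
    w, v = np.linalg.eigh(U)
    order = np.argsort(w)[::-1]
    return ScalingOperator(M, R, U, w[order], v[:, order])


def transform_points_to_xi(points: np.ndarray, growth: MeanGrowth, t: float) -> np.ndarray:
    """xi-representation of arbitrary physical points at stage t:
    xi = L(t)^-1 (p - xbar(t)).  Used e.g. for expression-signal coordinates."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    Linv = np.linalg.inv(growth.L_at(t))
    return (p - growth.centroid_at(t)) @ Linv.T


# ---------------------------------------------------------------------------
# cached fields for region scans
# ---------------------------------------------------------------------------

class FieldCache:
    """Precomputed positions and deformation gradients on a master lattice
    over the full initial outline, enabling cheap recomputation of
    region-restricted average growth and trajectories.

    Region scans re-derive C0, Fbar, L and the centroid path on each
    candidate sub-region; caching phi and F on a fixed lattice turns each
    restriction into masked averages plus linear interpolation.
    """

    def __init__(self, dmap, outline: TissueOutline,
                 stages: Sequence[float] | None = None,
                 spacing: float | None = None):
        self.map = dmap
        self.outline = outline
        self.stages = np.asarray(
            stages if stages is not None else dmap.stage_grid.stages, float)
        spacing = spacing or _default_spacing(outline.polygon, 40)
        self.points = lattice_in_polygon(outline.polygon, spacing)
        self.pos, self.F = dmap.gradient_trajectory(self.points, self.stages)
        self.detF = np.linalg.det(self.F)
        nt = len(self.stages)
        self._interp = LinearNDInterpolator(
            self.points, self.pos.reshape(len(self.points), nt * 2))

    def positions(self, X: np.ndarray, stages) -> np.ndarray:
        """Interpolated physical trajectories of material points X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        vals = self._interp(X)
        if np.any(np.isnan(vals)):
            # points marginally outside the lattice hull: snap to nearest node
            bad = np.isnan(vals).any(axis=1)
            d = np.linalg.norm(self.points[None] - X[bad, None], axis=-1)
            vals[bad] = self.pos.reshape(len(self.points), -1)[np.argmin(d, axis=1)]
        full = vals.reshape(len(X), len(self.stages), 2)
        stages = np.asarray(stages, float)
        if stages.shape == self.stages.shape and np.allclose(stages, self.stages):
            return full
        idx = np.searchsorted(self.stages, stages)
        return full[:, np.clip(idx, 0, len(self.stages) - 1)]

    def restricted(self, region: Polygon, seed_spacing: float = 0.04
                   ) -> tuple[MeanGrowth, XiDynamics]:
        """Average growth and xi dynamics recomputed on a sub-region."""
        import shapely
        mask = shapely.contains_xy(region, self.points[:, 0], self.points[:, 1])
        if mask.sum() < 4:
            raise ValueError("empty or near-empty region restriction")
        Fbar = self.F[mask].mean(axis=0)
        w = self.detF[mask]
        centroid = np.einsum("nt,nti->ti", w, self.pos[mask]) / w.sum(axis=0)[:, None]
        ring = resample_ring(np.asarray(region.exterior.coords)[:-1], 200)
        C0 = centroid_size(ring)
        growth = MeanGrowth(self.stages, C0, Fbar, centroid)
        sub_outline = TissueOutline(self.outline.stage, Polygon(ring))
        xi_poly = growth.xi_outline(sub_outline)
        seeds = lattice_in_polygon(xi_poly, seed_spacing)
        dyn = XiDynamics(self.map, growth, sub_outline, seeds,
                         positions=self.positions)
        return growth, dyn
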