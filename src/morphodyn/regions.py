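"""Region-restricted comparison of rescaled dynamics between species.

One species' bud may contain prospective tissue the other's lacks, so
conservation of rescaled dynamics is expected only for anatomically
corresponding regions.  A candidate sub-region of the reference species'
bud is parameterized by (alpha, beta, theta):

  * theta rotates the P-D comparison axis,
  * beta offsets the axis origin along the A-P direction (the chord of the
    outline along the shifted axis sets the region's proximo-distal span),
  * alpha keeps the distal fraction of that chord.

For each candidate region the rescaling is recomputed from scratch on the
region (its own C0, Fbar, L, centroid path) and the mean trajectory
distance to the other species is minimized over target stages per source
stage; eta is the temporal mean of those minima.  Overfitting of the axis
angle is measured by the coefficient of variation of theta*(beta) across
the beta grid: small regions can be made to match by tuning the axis, and
that shows up as a beta-sensitive optimal angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Polygon

from .rescaling import FieldCache, XiDynamics
from .sync import overlap_region

__all__ = ["RegionParams", "region_from_params", "eta_between",
           "RegionComparer", "cv_overfit", "scan_alpha"]


@dataclass(frozen=True)
class RegionParams:
    alpha: float          # distal fraction retained, (0, 1]
    beta: float = 0.0     # A-P axis-origin offset (same units as the outline)
    theta: float = 0.0    # axis rotation, radians in (-pi/2, pi/2]

    def __post_init__(self):
        if not 0 < self.alpha <= 1 + 1e-9:
            raise ValueError("alpha must be in (0, 1]")
        object.__setattr__(self, "alpha", min(float(self.alpha), 1.0))
        if not -np.pi / 2 < self.theta <= np.pi / 2:
            raise ValueError("theta must be in (-pi/2, pi/2]")


def region_from_params(outline_polygon: Polygon, p: RegionParams) -> Polygon:
    """Clip an outline to the distal-``alpha`` part of its chord along the
    rotated, offset P-D axis.  Returns a simple polygon."""
    c = outline_polygon.centroid
    u = np.array([np.cos(p.theta), np.sin(p.theta)])          # P-D axis
    w = np.array([-np.sin(p.theta), np.cos(p.theta)])         # A-P normal
    origin = np.array([c.x, c.y]) + p.beta * w
    minx, miny, maxx, maxy = outline_polygon.bounds
    span = max(maxx - minx, maxy - miny) * 2
    line = LineString([origin - span * u, origin + span * u])
    chord = line.intersection(outline_polygon)
    if chord.is_empty:
        raise ValueError("axis line misses the outline (beta too large)")
    pts = np.asarray(
        max(chord.geoms, key=lambda g: g.length).coords
        if chord.geom_type == "MultiLineString" else chord.coords)
    s = (pts - origin) @ u
    s_min, s_max = float(s.min()), float(s.max())
    cut = s_max - p.alpha * (s_max - s_min)
    # half plane {x : (x - origin) . u >= cut}
    far = s_max + span
    lo, hi = -span, span
    corners = [origin + cut * u + lo * w, origin + far * u + lo * w,
               origin + far * u + hi * w, origin + cut * u + hi * w]
    region = outline_polygon.intersection(Polygon(corners))
    if region.is_empty or region.area <= 0:
        raise ValueError("empty region for the given parameters")
    if region.geom_type == "MultiPolygon":
        region = max(region.geoms, key=lambda g: g.area)
    return region


def eta_between(dyn_src: XiDynamics, dyn_tgt: XiDynamics,
                source_stages: np.ndarray | None = None,
                seed_spacing: float = 0.05) -> float:
    """Temporal mean over source stages of the minimal trajectory distance
    to any target stage, with the seed set Omega fixed at the initial
    stages (overlap of both xi outlines)."""
    _, seeds = overlap_region(dyn_src.xi_outline, dyn_tgt.xi_outline,
                              spacing=seed_spacing)
    xs = dyn_src.trajectories(seeds)      # (n, nS, 2)
    xt = dyn_tgt.trajectories(seeds)      # (n, nT, 2)
    delta = np.linalg.norm(xs[:, :, None, :] - xt[:, None, :, :], axis=-1).mean(axis=0)
    if source_stages is not None:
        m = np.isin(np.round(dyn_src.stages, 9), np.round(source_stages, 9))
        if not m.any():
            m = (dyn_src.stages >= source_stages.min() - 1e-9) & \
                (dyn_src.stages <= source_stages.max() + 1e-9)
        delta = delta[m]
    return float(delta.min(axis=1).mean())


class RegionComparer:
    """eta(alpha, beta, theta) evaluator over cached deformation fields.

    ``cache_src`` covers the species whose bud is being restricted (the one
    that may contain extra proximal tissue); ``dyn_tgt`` is the other
    species' dynamics on its full bud.  ``period`` optionally limits the
    source stages entering the temporal average; ``mirrored=True`` swaps
    the roles in the distance argmin (the eta-tilde direction: target-grid
    stages become the source of the temporal average).
    """

    def __init__(self, cache_src: FieldCache, dyn_tgt: XiDynamics,
                 period: tuple[float, float] | None = None,
                 seed_spacing: float = 0.05,
                 region_seed_spacing: float = 0.04,
                 mirrored: bool = False):
        self.cache_src = cache_src
        self.dyn_tgt = dyn_tgt
        self.period = period
        self.seed_spacing = seed_spacing
        self.region_seed_spacing = region_seed_spacing
        self.mirrored = mirrored
        self._dyn_memo: dict[tuple[float, float, float], XiDynamics] = {}

    def restricted_dynamics(self, p: RegionParams) -> XiDynamics:
        key = (round(p.alpha, 12), round(p.beta, 12), round(p.theta, 12))
        if key not in self._dyn_memo:
            region = region_from_params(self.cache_src.outline.polygon, p)
            _, dyn = self.cache_src.restricted(region, self.region_seed_spacing)
            self._dyn_memo[key] = dyn
        return self._dyn_memo[key]

    def eta(self, alpha: float, beta: float = 0.0, theta: float = 0.0) -> float:
        p = RegionParams(alpha, beta, theta)
        dyn_src = self.restricted_dynamics(p)
        stages = None
        if self.period is not None:
            lo, hi = self.period
            base = self.dyn_tgt.stages if self.mirrored else dyn_src.stages
            stages = base[(base >= lo - 1e-9) & (base <= hi + 1e-9)]
        if self.mirrored:
            return eta_between(self.dyn_tgt, dyn_src, stages, self.seed_spacing)
        return eta_between(dyn_src, self.dyn_tgt, stages, self.seed_spacing)

    def theta_star(self, alpha: float, beta: float,
                   theta_grid: Sequence[float]) -> tuple[float, float]:
        """(theta*, eta at theta*) minimizing eta over the theta grid."""
        etas = [self.eta(alpha, beta, th) for th in theta_grid]
        k = int(np.argmin(etas))
        return float(theta_grid[k]), float(etas[k])


def cv_overfit(theta_stars: Sequence[float]) -> float:
    """Coefficient of variation sqrt(Var[theta*]) / E[theta*] across the
    beta grid (population variance).  Undefined (NaN, with a warning) when
    the mean optimal angle is zero."""
    th = np.asarray(theta_stars, dtype=float)
    mean = th.mean()
    if mean == 0:
        warnings.warn("E[theta*] = 0: CV undefined")
        return float("nan")
    return float(np.sqrt(np.var(th)) / mean)


def scan_alpha(comparer: RegionComparer, alpha_grid: Sequence[float],
               beta_grid: Sequence[float], theta_grid: Sequence[float],
               eta_threshold: float | None = None,
               cv_threshold: float | None = None) -> dict:
    """min_{beta,theta} eta(alpha) and CV_beta[theta*](alpha) curves, plus
    the alpha band where both fall below the configured thresholds."""
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    min_eta = np.empty(len(alpha_grid))
    cv = np.empty(len(alpha_grid))
    records = []
    for i, a in enumerate(alpha_grid):
        stars, best = [], []
        for b in beta_grid:
            th, e = comparer.theta_star(a, b, theta_grid)
            stars.append(th)
            best.append(e)
            records.append({"alpha": float(a), "beta": float(b),
                            "theta_star": th, "eta": e})
        min_eta[i] = np.min(best)
        cv[i] = cv_overfit(stars)
    out = {"alpha": alpha_grid, "min_eta": min_eta, "cv": cv, "records": records}
    if eta_threshold is not None and cv_threshold is not None:
        band = (min_eta <= eta_threshold) & (np.nan_to_num(cv, nan=np.inf) <= cv_threshold)
        out["band"] = alpha_grid[band]
    return out
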