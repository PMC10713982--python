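"""Cross-species synchronization of developmental clocks.

Two species' staging scales are charts on one abstract developmental clock.
The chart transition (composite stage map) is estimated by matching
rescaled-trajectory snapshots: for every stage pair the distance

    delta(t_A, t_B) = < | xi_A(xi0_i, t_A) - xi_B(xi0_i, t_B) | >_{i in Omega}

is averaged over a fixed seed set Omega (the overlap of both species'
initial outlines in xi space, typically restricted to the prospective
autopod + zeugopod).  Row/column argmins of the delta matrix give the
composite maps in both directions; where the underlying dynamics are
conserved these are monotone, continuous and mutually inverse, and the
valid range plus a linear stage correspondence are extracted from them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from .datamodel import StageGrid, lattice_in_polygon
from .rescaling import XiDynamics, _interp_array

__all__ = [
    "overlap_region", "trajectory_distance", "distance_matrix",
    "TrajectoryDistanceMatrix", "CompositeStageMap", "composite_stage_maps",
    "validity_range", "fit_linear_correspondence", "select_initial_stages",
]


def overlap_region(outline_A_xi: Polygon, outline_B_xi: Polygon,
                   spacing: float = 0.05) -> tuple[Polygon, np.ndarray]:
    """Intersection of two xi-space outlines and a regular seed lattice in it."""
    inter = outline_A_xi.intersection(outline_B_xi)
    if inter.is_empty or inter.area <= 0:
        raise ValueError("xi-space outlines do not overlap")
    if inter.geom_type == "MultiPolygon":
        inter = max(inter.geoms, key=lambda g: g.area)
    seeds = lattice_in_polygon(inter, spacing)
    if len(seeds) == 0:
        raise ValueError("overlap region too small for the seed lattice")
    return inter, seeds


def _snapshots(dyn: XiDynamics, seeds: np.ndarray) -> np.ndarray:
    """xi positions (n_seeds, n_stages, 2) with NaN for unusable seeds."""
    return dyn.trajectories(seeds)


def _check_conventions(dyn_A: XiDynamics, dyn_B: XiDynamics) -> None:
    ea = getattr(getattr(dyn_A, "growth", None), "estimator", None)
    eb = getattr(getattr(dyn_B, "growth", None), "estimator", None)
    if ea is not None and eb is not None and ea != eb:
        warnings.warn(
            f"comparing xi dynamics with different growth estimators "
            f"({ea} vs {eb}); rescaled trajectories are only comparable when "
            f"both species use the same convention")


def trajectory_distance(dyn_A: XiDynamics, dyn_B: XiDynamics,
                        t_A: float, t_B: float, seeds: np.ndarray,
                        max_excluded: float = 0.10) -> float:
    """delta(t_A, t_B): mean Euclidean xi distance over the seed set.
    Symmetric in species order; seeds with a missing trajectory are excluded
    (error if more than ``max_excluded`` of them are)."""
    _check_conventions(dyn_A, dyn_B)
    a = dyn_A.at_stage(seeds, t_A)
    b = dyn_B.at_stage(seeds, t_B)
    d = np.linalg.norm(a - b, axis=1)
    bad = np.isnan(d)
    if bad.mean() > max_excluded:
        raise ValueError(f"{bad.sum()}/{len(d)} seeds lack trajectories")
    if bad.any():
        warnings.warn(f"excluded {int(bad.sum())} seed(s) without trajectories")
    return float(np.mean(d[~bad]))


@dataclass
class TrajectoryDistanceMatrix:
    stages_A: np.ndarray
    stages_B: np.ndarray
    delta: np.ndarray           # (nA, nB), dimensionless xi units
    omega_seeds: np.ndarray


def distance_matrix(dyn_A: XiDynamics, dyn_B: XiDynamics,
                    seeds: np.ndarray,
                    max_excluded: float = 0.10) -> TrajectoryDistanceMatrix:
    """delta over the full stage-grid product of both dynamics."""
    _check_conventions(dyn_A, dyn_B)
    xa = _snapshots(dyn_A, seeds)          # (n, nA, 2)
    xb = _snapshots(dyn_B, seeds)          # (n, nB, 2)
    bad = np.isnan(xa).any(axis=(1, 2)) | np.isnan(xb).any(axis=(1, 2))
    if bad.mean() > max_excluded:
        raise ValueError(f"{bad.sum()}/{len(bad)} seeds lack trajectories")
    if bad.any():
        warnings.warn(f"excluded {int(bad.sum())} seed(s) without trajectories")
        xa, xb = xa[~bad], xb[~bad]
    diff = xa[:, :, None, :] - xb[:, None, :, :]
    delta = np.linalg.norm(diff, axis=-1).mean(axis=0)
    return TrajectoryDistanceMatrix(dyn_A.stages.copy(), dyn_B.stages.copy(),
                                    delta, seeds[~bad] if bad.any() else seeds)


@dataclass
class CompositeStageMap:
    """Discrete chart transition t_target = psi_target o psi_source^-1."""

    direction: str                       # "AtoB" or "BtoA"
    source_stages: np.ndarray
    target_stages: np.ndarray            # argmin match per source stage
    target_grid: np.ndarray = field(repr=False, default=None)

    @property
    def step_source(self) -> float:
        return float(np.median(np.diff(self.source_stages)))

    @property
    def step_target(self) -> float:
        return float(np.median(np.diff(self.target_grid)))

    def __call__(self, t: float) -> float:
        """Piecewise-constant lookup at the nearest source stage."""
        k = int(np.argmin(np.abs(self.source_stages - t)))
        return float(self.target_stages[k])


def composite_stage_maps(matrix: TrajectoryDistanceMatrix
                         ) -> tuple[CompositeStageMap, CompositeStageMap]:
    """Per-row and per-column argmins of the delta matrix (ties broken
    toward the earlier stage), giving both directions of the stage map."""
    jA = np.argmin(matrix.delta, axis=1)      # first minimum = earlier stage
    jB = np.argmin(matrix.delta, axis=0)
    ab = CompositeStageMap("AtoB", matrix.stages_A.copy(),
                           matrix.stages_B[jA], matrix.stages_B.copy())
    ba = CompositeStageMap("BtoA", matrix.stages_B.copy(),
                           matrix.stages_A[jB], matrix.stages_A.copy())
    return ab, ba


def _prefix_ok(cmap: CompositeStageMap, tol: float) -> np.ndarray:
    """Per-source-stage flag: correspondence up to here is monotone
    (non-decreasing) with jumps bounded by the nominal increment + tol
    target-grid steps."""
    t = cmap.target_stages
    inc = np.diff(t) / cmap.step_target
    nominal = max(np.median(inc), 0.0)
    ok_step = (inc >= -1e-9) & (inc <= nominal + tol + 1e-9)
    good = np.concatenate([[True], np.cumprod(ok_step).astype(bool)])
    return good


def validity_range(map_AB: CompositeStageMap, map_BA: CompositeStageMap,
                   tol: float = 1.0) -> tuple[float, float]:
    """Largest initial stage segment on which both composite maps are
    monotone with bounded jumps and mutually inverse within tolerance.

    Returns the end stages (t_A_end, t_B_end).  ``tol`` is in grid steps;
    the round-trip slack is tol source steps plus one target step (the
    discretization floor of the argmin correspondence).
    """
    okA = _prefix_ok(map_AB, tol)
    okB = _prefix_ok(map_BA, tol)
    rt_tol_A = tol * map_AB.step_source + map_AB.step_target
    rt_tol_B = tol * map_BA.step_source + map_BA.step_target
    rtA = np.array([abs(map_BA(tb) - ta) <= rt_tol_A
                    for ta, tb in zip(map_AB.source_stages, map_AB.target_stages)])
    rtB = np.array([abs(map_AB(ta) - tb) <= rt_tol_B
                    for tb, ta in zip(map_BA.source_stages, map_BA.target_stages)])
    endA = _last_true_prefix(okA & rtA)
    endB = _last_true_prefix(okB & rtB)
    return (float(map_AB.source_stages[endA]) if endA >= 0 else float("nan"),
            float(map_BA.source_stages[endB]) if endB >= 0 else float("nan"))


def _last_true_prefix(flags: np.ndarray) -> int:
    if not flags[0]:
        return -1
    bad = np.nonzero(~flags)[0]
    return int(bad[0] - 1) if bad.size else len(flags) - 1


def fit_linear_correspondence(cmap: CompositeStageMap,
                              stage_range: tuple[float, float] | None = None
                              ) -> tuple[float, float, float]:
    """Least-squares line t_target ~ slope * t_source + intercept over the
    given source-stage range; returns (slope, intercept, max_residual)."""
    s, t = cmap.source_stages, cmap.target_stages
    if stage_range is not None:
        m = (s >= stage_range[0] - 1e-12) & (s <= stage_range[1] + 1e-12)
        s, t = s[m], t[m]
    if len(s) < 3:
        raise ValueError("need at least 3 stage pairs for a linear fit")
    coef = np.polyfit(s, t, 1)
    resid = t - np.polyval(coef, s)
    return float(coef[0]), float(coef[1]), float(np.max(np.abs(resid)))


# ---------------------------------------------------------------------------
# initial-stage selection
# ---------------------------------------------------------------------------

def select_initial_stages(build_dynamics, candidates_A: Sequence[float],
                          candidates_B: Sequence[float],
                          paramsets: Sequence[tuple[float, float]],
                          theta_grid: Sequence[float]) -> dict:
    """Choose the initial-stage pair whose rescaled dynamics agree best.

    ``build_dynamics(t0_A, t0_B)`` must return a RegionComparer-style object
    with an ``eta(alpha, beta, theta)`` method (dynamics re-referenced to
    those initial stages).  For every candidate pair, min over theta of eta
    is computed for each (alpha, beta) parameter set; candidates are ranked
    by the median of those minima (SD reported alongside).
    """
    table = []
    for t0_A in candidates_A:
        for t0_B in candidates_B:
            comparer = build_dynamics(t0_A, t0_B)
            vals = []
            for alpha, beta in paramsets:
                etas = [comparer.eta(alpha, beta, th) for th in theta_grid]
                vals.append(float(np.min(etas)))
            table.append({
                "t0_A": float(t0_A), "t0_B": float(t0_B),
                "median": float(np.median(vals)), "sd": float(np.std(vals, ddof=1)),
                "values": vals,
            })
    best = min(table, key=lambda r: r["median"])
    return {"best": (best["t0_A"], best["t0_B"]), "table": table}
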