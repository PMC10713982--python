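"""Smooth tissue deformation maps fitted from labeled-spot correspondences.

Each stage interval gets an independent smooth 2D->2D regression
(affine mean by ordinary least squares + a Gaussian-process residual field
with an RBF kernel whose hyperparameters are selected by marginal-likelihood
maximization).  Interval maps are chained into a composite map
x = phi(X, t) over the full stage range; within an interval the position is
linearly interpolated in displacement, mirroring how spot positions between
measurements are interpolated.

The composite map supports evaluation, analytic Jacobians (deformation
gradient F = d phi / d X), Newton inversion, and bootstrap refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .datamodel import IntervalDataset, StageGrid, TissueOutline, lattice_in_polygon


class FoldWarning(UserWarning):
    """A fitted map has det F <= 0 somewhere on the evaluation grid."""


class InversionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# per-interval smooth map
# ---------------------------------------------------------------------------

@dataclass
class SmoothIntervalMap:
    """Differentiable map for one stage interval: x = A X + b + GP residual."""

    interval_index: int
    stage_start: float
    stage_end: float
    A: np.ndarray                      # (2, 2) affine linear part
    b: np.ndarray                      # (2,) affine offset
    X_train: np.ndarray                # (n, 2) training inputs
    alpha: np.ndarray                  # (n, 2) kernel weights (zero rows => pure affine)
    signal_var: float                  # RBF amplitude sigma_f^2
    length_scale: float                # RBF length scale, um
    fit_metadata: dict = field(default_factory=dict)

    def _k(self, X: np.ndarray) -> np.ndarray:
        if self.X_train.size == 0:
            return np.zeros((len(X), 0))
        d2 = np.sum((X[:, None, :] - self.X_train[None, :, :]) ** 2, axis=-1)
        return self.signal_var * np.exp(-0.5 * d2 / self.length_scale**2)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.A.T + self.b + self._k(X) @ self.alpha

    def jacobian(self, X: np.ndarray) -> np.ndarray:
        """Analytic Jacobian d x / d X, shape (n, 2, 2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        J = np.broadcast_to(self.A, (len(X), 2, 2)).copy()
        if self.X_train.size:
            k = self._k(X)                                        # (n, m)
            diff = X[:, None, :] - self.X_train[None, :, :]       # (n, m, 2)
            # d k_i / d X = -k_i * (X - X_i) / l^2 ; J += sum_i alpha_i outer dk_i
            dk = -(k[:, :, None] * diff) / self.length_scale**2   # (n, m, 2)
            J += np.einsum("nmj,mc->ncj", dk, self.alpha)
        return J


def fit_interval_map(
    data: IntervalDataset,
    prior: dict | None = None,
    seed: int = 0,
) -> SmoothIntervalMap:
    """Fit a smooth map to one interval's (X_i, x_i) pairs.

    The mean is an affine transform fitted by least squares (so exact affine
    data are reproduced exactly); the residual displacement field is a
    per-component GP with a shared isotropic RBF kernel plus white noise.
    Hyperparameters maximize the marginal likelihood; the fit is deterministic
    given ``seed`` (which only feeds optimizer restarts).

    Raises on rank-deficient (collinear) X configurations; warns with
    :class:`FoldWarning` if det F <= 0 anywhere on a grid over the data hull.
    """
    X, x = data.X, data.x
    if data.n_pairs < 3:
        raise ValueError("need at least 3 pairs for an affine fit")
    H = np.column_stack([X, np.ones(len(X))])
    if np.linalg.matrix_rank(H) < 3:
        raise np.linalg.LinAlgError("degenerate collinear landmark configuration")
    coef, *_ = np.linalg.lstsq(H, x, rcond=None)
    A, b = coef[:2].T, coef[2]
    resid = x - (X @ A.T + b)

    prior = dict(prior or {})
    diam = float(np.linalg.norm(np.ptp(X, axis=0))) or 1.0
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms < 1e-9:
        # exact affine data: no residual field to learn
        m = SmoothIntervalMap(data.interval_index, data.stage_start, data.stage_end,
                              A, b, np.empty((0, 2)), np.empty((0, 2)),
                              0.0, diam, {"mean_residual": 0.0, "noise_level": 0.0})
        _fold_check(m, X)
        return m

    # the marginal-likelihood surface has a spurious "all noise" optimum at
    # large length scales; start from several log-spaced scales and keep the
    # best evidence
    ls_inits = prior.get("length_scale_inits", (diam / 16, diam / 6, diam / 2))
    gp = None
    for ls0 in np.atleast_1d(ls_inits):
        kernel = (
            ConstantKernel(rms**2, (rms**2 * 1e-4, rms**2 * 1e4))
            * RBF(ls0, (diam / 50, diam * 10))
            + WhiteKernel(prior.get("noise_level", rms**2 / 4),
                          (rms**2 * 1e-6, rms**2 * 1e2))
        )
        cand = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, alpha=0.0,
            n_restarts_optimizer=int(prior.get("n_restarts", 0)),
            random_state=np.random.RandomState(seed),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter
            cand.fit(X, resid)
        if gp is None or cand.log_marginal_likelihood_value_ > gp.log_marginal_likelihood_value_:
            gp = cand
    k = gp.kernel_
    signal_var = float(k.k1.k1.constant_value)
    length_scale = float(k.k1.k2.length_scale)
    noise = float(k.k2.noise_level)
    m = SmoothIntervalMap(
        data.interval_index, data.stage_start, data.stage_end, A, b,
        X.copy(), np.atleast_2d(gp.alpha_).reshape(len(X), 2),
        signal_var, length_scale,
        {"noise_level": noise, "log_marginal_likelihood": float(gp.log_marginal_likelihood_value_)},
    )
    m.fit_metadata["mean_residual"] = float(np.mean(np.linalg.norm(m(X) - x, axis=1)))
    _fold_check(m, X)
    return m


def _fold_check(m: SmoothIntervalMap, X: np.ndarray, n: int = 12) -> None:
    lo, hi = X.min(axis=0), X.max(axis=0)
    gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], n), np.linspace(lo[1], hi[1], n))
    J = m.jacobian(np.column_stack([gx.ravel(), gy.ravel()]))
    det = np.linalg.det(J)
    if np.any(det <= 0):
        i = int(np.argmin(det))
        warnings.warn(
            f"interval {m.interval_index}: fold detected (det F = {det[i]:.3g} at "
            f"({gx.ravel()[i]:.1f}, {gy.ravel()[i]:.1f}) um)", FoldWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# composite map
# ---------------------------------------------------------------------------

class DeformationMap:
    """Composite deformation map phi(X, t) chained from interval maps.

    ``stage_grid`` holds the K+1 interval endpoints; phi(X, t0) = X, and at
    interval boundaries composition is exact (the output of interval k is the
    input of interval k+1).  Within an interval positions follow linear
    displacement interpolation.
    """

    def __init__(self, interval_maps: Sequence[SmoothIntervalMap],
                 initial_domain: TissueOutline | None = None,
                 stage_grid: StageGrid | None = None):
        maps = sorted(interval_maps, key=lambda m: m.stage_start)
        for prev, nxt in zip(maps, maps[1:]):
            if not np.isclose(prev.stage_end, nxt.stage_start):
                raise ValueError(
                    f"interval gap/overlap between stages {prev.stage_end} and {nxt.stage_start}")
        self.interval_maps = maps
        self.initial_domain = initial_domain
        stages = [maps[0].stage_start] + [m.stage_end for m in maps]
        self.stage_grid = stage_grid or StageGrid("composite", np.asarray(stages))
        self._endpoints = np.asarray(stages)

    # -- protocol -----------------------------------------------------------
    @property
    def t0(self) -> float:
        return float(self._endpoints[0])

    @property
    def t_end(self) -> float:
        return float(self._endpoints[-1])

    def _locate(self, t: float) -> tuple[int, float]:
        eps = 1e-9 * (self.t_end - self.t0)
        if t < self.t0 - eps or t > self.t_end + eps:
            raise ValueError(f"stage {t} outside map range [{self.t0}, {self.t_end}]")
        t = min(max(t, self.t0), self.t_end)
        k = int(np.searchsorted(self._endpoints, t, side="right")) - 1
        k = min(k, len(self.interval_maps) - 1)
        frac = (t - self._endpoints[k]) / (self._endpoints[k + 1] - self._endpoints[k])
        return k, frac

    def __call__(self, X: np.ndarray, t: float) -> np.ndarray:
        return self.trajectory(X, [t])[:, 0, :]

    def trajectory(self, X: np.ndarray, stages: Sequence[float]) -> np.ndarray:
        """Positions of material points X at each requested stage, (n, T, 2).

        Walks the interval chain once; requested stages must be ascending.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        stages = np.asarray(stages, dtype=float)
        if np.any(np.diff(stages) < 0):
            raise ValueError("requested stages must be ascending")
        out = np.empty((len(X), len(stages), 2))
        cur = X.copy()
        nxt = None
        k_cur = -1
        for j, t in enumerate(stages):
            k, frac = self._locate(t)
            while k_cur < k:
                if k_cur >= 0:
                    cur = nxt if nxt is not None else self.interval_maps[k_cur](cur)
                k_cur += 1
                nxt = None
            if frac == 0.0:
                out[:, j] = cur
            else:
                if nxt is None:
                    nxt = self.interval_maps[k](cur)
                out[:, j] = cur + frac * (nxt - cur)
        return out

    def gradient(self, X: np.ndarray, t: float) -> np.ndarray:
        return self.gradient_trajectory(X, [t])[1][:, 0]

    def gradient_trajectory(self, X: np.ndarray, stages: Sequence[float]
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Positions and deformation gradients F(X, t) along the chain.

        Returns (pos (n,T,2), F (n,T,2,2)); F is the chain-rule product of
        per-interval analytic Jacobians, with the fractional interval
        contributing (1-frac) I + frac J.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        stages = np.asarray(stages, dtype=float)
        if np.any(np.diff(stages) < 0):
            raise ValueError("requested stages must be ascending")
        n = len(X)
        pos = np.empty((n, len(stages), 2))
        F = np.empty((n, len(stages), 2, 2))
        cur = X.copy()
        Fcur = np.broadcast_to(np.eye(2), (n, 2, 2)).copy()
        k_cur = -1
        nxt = Jn = None
        for j, t in enumerate(stages):
            k, frac = self._locate(t)
            while k_cur < k:
                if k_cur >= 0:
                    if nxt is None:
                        nxt = self.interval_maps[k_cur](cur)
                        Jn = self.interval_maps[k_cur].jacobian(cur)
                    cur, Fcur = nxt, np.einsum("nij,njk->nik", Jn, Fcur)
                k_cur += 1
                nxt = Jn = None
            if frac == 0.0:
                pos[:, j], F[:, j] = cur, Fcur
            else:
                if nxt is None:
                    nxt = self.interval_maps[k](cur)
                    Jn = self.interval_maps[k].jacobian(cur)
                pos[:, j] = cur + frac * (nxt - cur)
                Jmix = (1 - frac) * np.eye(2) + frac * Jn
                F[:, j] = np.einsum("nij,njk->nik", Jmix, Fcur)
        return pos, F

    # -- inversion ----------------------------------------------------------
    def invert(self, x: np.ndarray, t: float, tol: float = 1e-6,
               max_iter: int = 50) -> np.ndarray:
        """Material coordinates X with phi(X, t) = x (Newton iteration with
        coarse-grid initialization; see :func:`invert_map`)."""
        return invert_map(self, x, t, tol=tol, max_iter=max_iter)


def compose_maps(maps: Sequence[SmoothIntervalMap], grid: StageGrid | None = None,
                 initial_domain: TissueOutline | None = None) -> DeformationMap:
    """Chain contiguous interval maps into a composite DeformationMap."""
    return DeformationMap(maps, initial_domain=initial_domain, stage_grid=grid)


# ---------------------------------------------------------------------------
# local deformation summary
# ---------------------------------------------------------------------------

def local_deformation_summary(F: np.ndarray) -> tuple[float, float, float | None]:
    """(area_ratio, anisotropy_magnitude, orientation) from one 2x2 tensor.

    area_ratio = det F; principal stretches come from the right stretch
    tensor U = (F^T F)^(1/2); anisotropy magnitude = log(lambda1/lambda2);
    orientation is the major principal direction pushed forward into the
    deformed configuration, reported modulo pi (None at isotropy).
    """
    F = np.asarray(F, dtype=float).reshape(2, 2)
    det = float(np.linalg.det(F))
    if det <= 0:
        raise ValueError(f"invalid deformation tensor: det F = {det:.3g} <= 0")
    C = F.T @ F
    w, v = np.linalg.eigh(C)            # ascending eigenvalues of C = U^2
    lam2, lam1 = np.sqrt(w[0]), np.sqrt(w[1])
    mag = float(np.log(lam1 / lam2))
    if mag < 1e-12:
        return det, 0.0, None
    pushed = F @ v[:, 1]
    angle = float(np.arctan2(pushed[1], pushed[0]) % np.pi)
    return det, mag, angle


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_maps(datasets: Sequence[IntervalDataset], B: int = 150,
                   seed: int = 0, prior: dict | None = None,
                   initial_domain: TissueOutline | None = None,
                   grid: StageGrid | None = None) -> list[DeformationMap]:
    """Refit the full composite map on B datasets resampled with replacement
    (per interval, at the original n_pairs).  Degenerate replicates are
    skipped with a warning.  Default B = 150."""
    rng = np.random.default_rng(seed)
    replicates: list[DeformationMap] = []
    skipped = 0
    for b in range(B):
        try:
            fitted = []
            for ds in datasets:
                idx = rng.integers(0, ds.n_pairs, size=ds.n_pairs)
                sub = IntervalDataset(ds.interval_index, ds.stage_start, ds.stage_end,
                                      ds.X[idx], ds.x[idx])
                fitted.append(fit_interval_map(sub, prior=prior,
                                               seed=int(rng.integers(2**31 - 1))))
            replicates.append(compose_maps(fitted, grid=grid, initial_domain=initial_domain))
        except np.linalg.LinAlgError:
            skipped += 1
    if skipped:
        warnings.warn(f"bootstrap: skipped {skipped} degenerate replicate(s)")
    return replicates


def evaluation_lattice(outline: TissueOutline, spacing: float) -> np.ndarray:
    """Convenience: lattice points inside the initial outline."""
    return lattice_in_polygon(outline.polygon, spacing)


# ---------------------------------------------------------------------------
# protocol-level helpers (work on fitted and analytic maps alike)
# ---------------------------------------------------------------------------

def invert_map(dmap, x: np.ndarray, t: float, tol: float = 1e-6,
               max_iter: int = 50, grid_n: int = 25) -> np.ndarray:
    """Material coordinates X with phi(X, t) = x for any map implementing
    trajectory/gradient_trajectory, by Newton iteration initialized from a
    coarse grid over the initial domain."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    dom = getattr(dmap, "initial_domain", None)
    if dom is not None:
        lo, hi = dom.vertices.min(axis=0), dom.vertices.max(axis=0)
    elif getattr(dmap, "interval_maps", None) and dmap.interval_maps[0].X_train.size:
        pts = dmap.interval_maps[0].X_train
        lo, hi = pts.min(axis=0), pts.max(axis=0)
    else:
        lo = hi = None
    if lo is not None:
        gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], grid_n),
                             np.linspace(lo[1], hi[1], grid_n))
        cand = np.column_stack([gx.ravel(), gy.ravel()])
        mapped = dmap.trajectory(cand, [t])[:, 0]
        d = np.linalg.norm(mapped[None, :, :] - x[:, None, :], axis=-1)
        X = cand[np.argmin(d, axis=1)].copy()
    else:
        X = x.copy()
    for _ in range(max_iter):
        pos, F = dmap.gradient_trajectory(X, [t])
        r = x - pos[:, 0]
        if np.all(np.linalg.norm(r, axis=1) < tol):
            return X
        X = X + np.linalg.solve(F[:, 0], r[..., None])[..., 0]
    pos = dmap.trajectory(X, [t])[:, 0]
    worst = float(np.max(np.linalg.norm(x - pos, axis=1)))
    if worst >= tol:
        raise InversionError(f"Newton failed to converge; best residual {worst:.3g} um")
    return X


class RebasedMap:
    """View of a deformation map re-referenced to a later initial stage t0.

    Positions at t0 become the new material coordinates: the map inverts
    the parent at t0 once per evaluation batch and chains forward, with
    F'(X', t) = F(X, t) F(X, t0)^-1.  The initial domain is the parent
    outline advected to t0 (requires the parent to expose ``outline_at`` or
    an invertible composite chain)."""

    def __init__(self, parent, t0: float):
        self.parent = parent
        self._t0 = float(t0)
        stages = parent.stage_grid.stages
        keep = stages[stages > t0 + 1e-12]
        self.stage_grid = StageGrid(parent.stage_grid.species,
                                    np.concatenate([[t0], keep]))
        if hasattr(parent, "outline_at"):
            self.initial_domain = parent.outline_at(t0)
        elif parent.initial_domain is not None:
            v = parent.trajectory(parent.initial_domain.vertices, [t0])[:, 0]
            from shapely.geometry import Polygon as _Poly
            regions = {k: _Poly(parent.trajectory(
                np.asarray(p.exterior.coords)[:-1], [t0])[:, 0])
                for k, p in parent.initial_domain.regions.items()}
            self.initial_domain = TissueOutline(t0, _Poly(v), regions)
        else:
            self.initial_domain = None

    @property
    def t0(self) -> float:
        return self._t0

    def _material(self, X: np.ndarray) -> np.ndarray:
        return invert_map(self.parent, X, self._t0)

    def trajectory(self, X: np.ndarray, stages) -> np.ndarray:
        return self.parent.trajectory(self._material(X), stages)

    def __call__(self, X: np.ndarray, t: float) -> np.ndarray:
        return self.trajectory(X, [t])[:, 0]

    def gradient_trajectory(self, X: np.ndarray, stages):
        Xm = self._material(X)
        stages = np.asarray(stages, dtype=float)
        _, F0 = self.parent.gradient_trajectory(Xm, [self._t0])
        pos, F = self.parent.gradient_trajectory(Xm, stages)
        F0inv = np.linalg.inv(F0[:, 0])
        return pos, np.einsum("ntij,njk->ntik", F, F0inv)

    def gradient(self, X: np.ndarray, t: float) -> np.ndarray:
        return self.gradient_trajectory(X, [t])[1][:, 0]


def reconstruct_map(records, grid: StageGrid, outline: TissueOutline | None = None,
                    prior: dict | None = None, seed: int = 0) -> DeformationMap:
    """Full reconstruction pipeline: integrate spot records into interval
    pair sets on the stage grid, fit each interval's smooth map, and chain
    them into a composite deformation map."""
    from .datamodel import build_interval_datasets
    datasets, empties = build_interval_datasets(records, grid)
    if empties:
        warnings.warn(f"{len(empties)} empty interval(s): "
                      f"{[(w.stage_start, w.stage_end) for w in empties]}")
    rng = np.random.default_rng(seed)
    fitted = [fit_interval_map(ds, prior=prior, seed=int(rng.integers(2**31 - 1)))
              for ds in datasets]
    return compose_maps(fitted, grid=grid, initial_domain=outline)
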