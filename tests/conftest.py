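"""Shared fixtures: analytic toy maps and synthetic scenarios.

Heavy scenario fixtures are session-scoped so acceptance-style tests can
share fitted maps and decompositions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from shapely.geometry import Polygon

import morphodyn as md
from morphodyn.datamodel import StageGrid, TissueOutline

warnings.filterwarnings("ignore", category=md.FoldWarning)


class FnMap:
    """Analytic deformation map defined by a closed-form function x = f(X, t).

    Implements the map protocol (trajectory / gradient_trajectory) with
    central finite differences for the gradient, for use as an independent
    test article against the pipeline.
    """

    def __init__(self, fn, stages, outline: TissueOutline, h: float = 0.5,
                 jac=None):
        self.fn = fn
        self.jac = jac          # optional analytic Jacobian (X, t) -> (n,2,2)
        self.stage_grid = StageGrid("toy", np.asarray(stages, float))
        self.initial_domain = outline
        self.h = h

    @property
    def t0(self):
        return float(self.stage_grid.stages[0])

    def __call__(self, X, t):
        return self.fn(np.atleast_2d(np.asarray(X, float)), t)

    def trajectory(self, X, stages):
        X = np.atleast_2d(np.asarray(X, float))
        return np.stack([self.fn(X, t) for t in np.asarray(stages, float)], axis=1)

    def gradient_trajectory(self, X, stages):
        X = np.atleast_2d(np.asarray(X, float))
        stages = np.asarray(stages, float)
        pos = self.trajectory(X, stages)
        F = np.empty((len(X), len(stages), 2, 2))
        for j, t in enumerate(stages):
            if self.jac is not None:
                F[:, j] = self.jac(X, t)
            else:
                for k, e in enumerate(np.eye(2)):
                    F[:, j, :, k] = (self.fn(X + self.h * e, t)
                                     - self.fn(X - self.h * e, t)) / (2 * self.h)
        return pos, F

    def gradient(self, X, t):
        return self.gradient_trajectory(X, [t])[1][:, 0]


def rect_outline(w=600.0, h=400.0, stage=0.0) -> TissueOutline:
    """Axis-aligned rectangle centered at the origin (um)."""
    ring = np.array([[-w / 2, -h / 2], [w / 2, -h / 2], [w / 2, h / 2], [-w / 2, h / 2]])
    return TissueOutline(stage, Polygon(ring))


def analytic_nonlinear_map(g1=0.15, g2=0.08, c=0.5, R=300.0,
                           stages=np.linspace(0.0, 4.0, 17)):
    """Closed-form smooth nonlinear growth map with an analytic Jacobian:
    anisotropic linear growth plus a trigonometric displacement field."""

    def fn(X, t):
        x1 = X[:, 0] * (1 + g1 * t) + 0.1 * c * t * R * np.sin(X[:, 0] / R) * np.cos(X[:, 1] / R)
        x2 = X[:, 1] * (1 + g2 * t) + 0.08 * c * t * R * np.cos(X[:, 0] / R) * np.sin(X[:, 1] / R)
        return np.column_stack([x1, x2])

    def jac(X, t):
        J = np.zeros((len(X), 2, 2))
        J[:, 0, 0] = (1 + g1 * t) + 0.1 * c * t * np.cos(X[:, 0] / R) * np.cos(X[:, 1] / R)
        J[:, 0, 1] = -0.1 * c * t * np.sin(X[:, 0] / R) * np.sin(X[:, 1] / R)
        J[:, 1, 0] = -0.08 * c * t * np.sin(X[:, 0] / R) * np.sin(X[:, 1] / R)
        J[:, 1, 1] = (1 + g2 * t) + 0.08 * c * t * np.cos(X[:, 0] / R) * np.cos(X[:, 1] / R)
        return J

    return FnMap(fn, stages, rect_outline(600, 400), jac=jac)


@pytest.fixture(scope="session")
def smooth_growth_map():
    return analytic_nonlinear_map()


@pytest.fixture(scope="session")
def default_flow():
    return md.make_archetype_flow()


@pytest.fixture(scope="session")
def species_pair():
    """Two full-bud species sharing the default flow (default warps)."""
    flow, map_A, map_B = md.two_species_scenario(seed=6)
    return flow, map_A, map_B


@pytest.fixture(scope="session")
def fitted_species_A(species_pair):
    """Species A fitted from a noisy 150-spots-per-interval experiment."""
    _, map_A, _ = species_pair
    records = md.sample_spots(map_A, md.uniform_design(150, seed=41))
    fitted = md.reconstruct_map(records, map_A.stage_grid, map_A.initial_domain, seed=41)
    return map_A, fitted


@pytest.fixture(scope="session")
def decomposed_species_A(species_pair):
    _, map_A, _ = species_pair
    stages = md.refine_stage_grid(map_A.stage_grid, 2)
    growth, dyn = md.decompose(map_A, stages=stages, seed_spacing=0.1)
    return map_A, growth, dyn
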