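"""Shared data model and I/O for landmark-based tissue morphodynamics.

Coordinate convention (both species): axis 1 = proximo-distal (distal
positive), axis 2 = antero-posterior (anterior positive), units of
micrometres on the frontal plane.  Stage values are unitless reals on each
species' own staging scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Polygon

SPOT_COLUMNS = ("individual_id", "stage", "spot_id", "pd_um", "ap_um")

SCHEMA_VERSION = "morphodyn-1"


class SchemaError(ValueError):
    """A table is missing required columns or has a malformed layout."""


@dataclass(frozen=True)
class SpotRecord:
    """One position measurement of one labeled cell spot.

    ``pos`` is (P-D, A-P) in micrometres on the frontal plane.
    """

    individual_id: str
    stage: float
    spot_id: str
    pos: tuple[float, float]

    def __post_init__(self):
        if not np.isfinite(self.stage):
            raise ValueError(f"non-finite stage for spot {self.spot_id!r}")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite position for spot {self.spot_id!r}")


@dataclass
class IntervalDataset:
    """Landmark correspondences (X_i, x_i) for one stage interval."""

    interval_index: int
    stage_start: float
    stage_end: float
    X: np.ndarray  # (n, 2) positions at stage_start, um
    x: np.ndarray  # (n, 2) positions at stage_end, um

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float).reshape(-1, 2)
        self.x = np.asarray(self.x, dtype=float).reshape(-1, 2)
        if self.X.shape != self.x.shape:
            raise ValueError("X and x must have matching shapes")
        if not self.stage_start < self.stage_end:
            raise ValueError("stage_start must be < stage_end")

    @property
    def n_pairs(self) -> int:
        return self.X.shape[0]


@dataclass
class EmptyIntervalWarning:
    """Explicit marker for a grid interval with no spanning spots."""

    interval_index: int
    stage_start: float
    stage_end: float


@dataclass
class TissueOutline:
    """Closed tissue boundary at one stage, with optional labeled sub-regions
    (e.g. prospective autopod / zeugopod)."""

    stage: float
    polygon: Polygon
    regions: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(np.asarray(self.polygon, dtype=float))
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("outline polygon must be simple with positive area")
        self.regions = {
            k: (p if isinstance(p, Polygon) else Polygon(np.asarray(p, float)))
            for k, p in self.regions.items()
        }

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.polygon.exterior.coords)[:-1]

    def scaled(self, factor: float, center: np.ndarray | None = None) -> "TissueOutline":
        """Similarity-scale the outline (and its regions) about ``center``."""
        c = np.zeros(2) if center is None else np.asarray(center, float)

        def _s(p):
            v = np.asarray(p.exterior.coords)[:-1]
            return Polygon(c + factor * (v - c))

        return TissueOutline(self.stage, _s(self.polygon),
                             {k: _s(p) for k, p in self.regions.items()})


@dataclass
class StageGrid:
    """Strictly increasing stage values for one species."""

    species: str
    stages: np.ndarray

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=float)
        if self.stages.ndim != 1 or self.stages.size < 2:
            raise ValueError("stage grid needs at least two stages")
        if not np.all(np.diff(self.stages) > 0):
            raise ValueError("stage grid must be strictly increasing")

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.stages)))

    def __len__(self) -> int:
        return self.stages.size


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_spot_table(path, dialect: dict | None = None) -> list[SpotRecord]:
    """Read a spot table (CSV/TSV with columns individual_id, stage, spot_id,
    pd_um, ap_um) into validated records, preserving row order."""
    sep = (dialect or {}).get("sep", None)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spot table missing column(s): {missing}")
    flip_ap = bool((dialect or {}).get("flip_ap", False))
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        pd_um, ap_um = float(row.pd_um), float(row.ap_um)
        if flip_ap:
            ap_um = -ap_um
        if not (np.isfinite(row.stage) and np.isfinite(pd_um) and np.isfinite(ap_um)):
            raise ValueError(f"non-finite value in spot table at row {i}")
        records.append(SpotRecord(str(row.individual_id), float(row.stage),
                                  str(row.spot_id), (pd_um, ap_um)))
    _check_unique(records)
    return records


def _check_unique(records: Sequence[SpotRecord]):
    keys = [(r.individual_id, r.spot_id, r.stage) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (individual_id, spot_id, stage) in dataset")


def write_spot_table(records: Sequence[SpotRecord], path) -> None:
    df = pd.DataFrame(
        [(r.individual_id, r.stage, r.spot_id, r.pos[0], r.pos[1]) for r in records],
        columns=SPOT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_outline_csv(path) -> list[TissueOutline]:
    """Outline rings stored long-form: stage, region, vertex_index, pd_um, ap_um.

    An empty/NaN ``region`` denotes the tissue boundary itself.
    """
    df = pd.read_csv(path)
    need = {"stage", "vertex_index", "pd_um", "ap_um"}
    if not need.issubset(df.columns):
        raise SchemaError(f"outline table missing column(s): {sorted(need - set(df.columns))}")
    if "region" not in df.columns:
        df["region"] = ""
    df["region"] = df["region"].fillna("")
    outlines = []
    for stage, g in df.groupby("stage", sort=True):
        ring = None
        regions = {}
        for region, gg in g.groupby("region"):
            gg = gg.sort_values("vertex_index")
            poly = Polygon(gg[["pd_um", "ap_um"]].to_numpy())
            if region == "":
                ring = poly
            else:
                regions[str(region)] = poly
        if ring is None:
            raise SchemaError(f"stage {stage}: no boundary ring (empty region field)")
        outlines.append(TissueOutline(float(stage), ring, regions))
    return outlines


def write_outline_csv(outlines: Sequence[TissueOutline], path) -> None:
    rows = []
    for o in outlines:
        for name, poly in [("", o.polygon), *o.regions.items()]:
            v = np.asarray(poly.exterior.coords)[:-1]
            for j, (a, b) in enumerate(v):
                rows.append((o.stage, name, j, a, b))
    pd.DataFrame(rows, columns=["stage", "region", "vertex_index", "pd_um", "ap_um"]).to_csv(
        path, index=False, float_format="%.17g")


def read_stage_grid(path) -> StageGrid:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return StageGrid(doc["species"], np.asarray(doc["stages"], dtype=float))


def write_stage_grid(grid: StageGrid, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"schema": SCHEMA_VERSION, "species": grid.species,
                        "stages": [float(s) for s in grid.stages]}, fh)


def write_json(obj: dict, path) -> None:
    obj = dict(obj)
    obj.setdefault("schema", SCHEMA_VERSION)
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# interval construction
# ---------------------------------------------------------------------------

def build_interval_datasets(
    records: Sequence[SpotRecord], grid: StageGrid
) -> tuple[list[IntervalDataset], list[EmptyIntervalWarning]]:
    """Integrate per-individual spot measurements into per-interval pair sets.

    For each consecutive grid interval [t_k, t_{k+1}], every spot whose
    measured stage span covers the interval contributes the pair
    (position at t_k, position at t_{k+1}); positions between an individual's
    measured stages are obtained by linear interpolation in stage, and
    extrapolation beyond the measured span is never performed.

    The result is deterministic and independent of input record order
    (records are sorted internally by (individual_id, spot_id, stage)).
    """
    _check_unique(records)
    by_spot: dict[tuple[str, str], list[SpotRecord]] = {}
    for r in sorted(records, key=lambda r: (r.individual_id, r.spot_id, r.stage)):
        by_spot.setdefault((r.individual_id, r.spot_id), []).append(r)

    datasets: list[IntervalDataset] = []
    warnings_: list[EmptyIntervalWarning] = []
    for k in range(len(grid) - 1):
        t0, t1 = grid.stages[k], grid.stages[k + 1]
        X_list, x_list = [], []
        for recs in by_spot.values():
            stages = np.array([r.stage for r in recs])
            if stages.size < 2 or stages.min() > t0 or stages.max() < t1:
                continue
            pos = np.array([r.pos for r in recs])
            X_list.append([np.interp(t0, stages, pos[:, 0]), np.interp(t0, stages, pos[:, 1])])
            x_list.append([np.interp(t1, stages, pos[:, 0]), np.interp(t1, stages, pos[:, 1])])
        if not X_list:
            warnings_.append(EmptyIntervalWarning(k + 1, float(t0), float(t1)))
            continue
        datasets.append(IntervalDataset(k + 1, float(t0), float(t1),
                                        np.array(X_list), np.array(x_list)))
    return datasets, warnings_


def points_in_polygon(points: np.ndarray, polygon: Polygon) -> np.ndarray:
    """Boolean mask of points strictly inside (or on) a polygon."""
    pts = np.asarray(points, dtype=float)
    return shapely.contains_xy(polygon, pts[:, 0], pts[:, 1])


def lattice_in_polygon(polygon: Polygon, spacing: float) -> np.ndarray:
    """Regular lattice points (given spacing) clipped to the polygon interior."""
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.arange(minx + spacing / 2, maxx, spacing)
    ys = np.arange(miny + spacing / 2, maxy, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if pts.size == 0:
        return np.empty((0, 2))
    mask = shapely.contains_xy(polygon, pts[:, 0], pts[:, 1])
    return pts[mask]
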