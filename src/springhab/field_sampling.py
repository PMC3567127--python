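"""Presence/pseudo-absence sampling design.

Observed fish locations carry ~0.5-1 m positional error and are patchily
distributed, so the design works at the patch level: polygons are drawn
around observation clusters (buffered unions), the same number of random
presence points is generated inside each patch as the mean number of fish
observed there across surveys, and background pseudo-absences are drawn
on wet cells outside every patch with a minimum spacing of one cell
(0.12 m) so that no cell is sampled twice and neighbouring samples do not
touch.  Each point is then attributed with the environmental value of the
cell containing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.ops import unary_union

from .raster_core import SpringbrookScene

__all__ = [
    "Patch",
    "PatchSet",
    "SampleSet",
    "CapacityError",
    "build_patches",
    "draw_presences",
    "draw_absences",
    "extract_covariates",
    "MIN_SPACING",
]

#: Minimum spacing between any two sample points (m) - one grid cell.
MIN_SPACING = 0.12

PRESENCE = "presence"
ABSENCE = "absence"


class CapacityError(RuntimeError):
    """The sampling region cannot hold the requested points at the spacing."""


@dataclass
class Patch:
    """One occupied patch: its polygon and per-survey observation counts."""

    polygon: shapely.Geometry
    survey_counts: dict[str, int]

    @property
    def mean_observed_count(self) -> float:
        """Mean fish count over the surveys in which the patch was occupied."""
        occupied = [c for c in self.survey_counts.values() if c > 0]
        return float(np.mean(occupied)) if occupied else 0.0

    @property
    def rounded_count(self) -> int:
        """Half-up rounding of the mean observed count."""
        return int(math.floor(self.mean_observed_count + 0.5))


@dataclass
class PatchSet:
    patches: list[Patch]
    surveys: tuple[str, ...]

    def union(self) -> shapely.Geometry:
        return unary_union([p.polygon for p in self.patches])

    def __len__(self) -> int:
        return len(self.patches)


def build_patches(observations: pd.DataFrame, buffer_radius: float = 0.5) -> PatchSet:
    """Merge observation points into occupied-patch polygons.

    Each point is buffered by ``buffer_radius`` and the buffers unioned,
    so observations within twice the radius of each other merge into one
    patch; larger clusters produce bigger patches.  Per-patch mean counts
    are computed across surveys (the ``survey`` column; a single implicit
    survey if absent).
    """
    if len(observations) == 0:
        raise ValueError("no observations to build patches from")
    obs = observations.copy()
    if "survey" not in obs.columns:
        obs["survey"] = "survey_1"
    if "count" not in obs.columns:
        obs["count"] = 1
    surveys = tuple(pd.unique(obs["survey"]))

    buffers = shapely.buffer(shapely.points(obs["x"].to_numpy(), obs["y"].to_numpy()),
                             buffer_radius)
    merged = unary_union(buffers)
    polygons = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]

    patches = []
    for poly in polygons:
        covered = shapely.covers(poly, shapely.points(obs["x"].to_numpy(),
                                                      obs["y"].to_numpy()))
        inside = obs[covered]
        counts = {s: int(inside.loc[inside["survey"] == s, "count"].sum())
                  for s in surveys}
        if sum(counts.values()) == 0:
            continue
        patches.append(Patch(poly, counts))
    return PatchSet(patches, surveys)


def _too_close(x: float, y: float, accepted_xy: list[tuple[float, float]],
               min_spacing: float) -> bool:
    if not accepted_xy:
        return False
    pts = np.asarray(accepted_xy)
    d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2
    return bool(np.min(d2) < min_spacing**2)


def draw_presences(patch_set: PatchSet, seed: int = 0,
                   min_spacing: float = MIN_SPACING,
                   scene: SpringbrookScene | None = None,
                   max_rejections: int = 10_000) -> pd.DataFrame:
    """Random presence points inside each patch, one per mean observed fish.

    Per patch, ``round(mean_observed_count)`` points are placed uniformly
    at random inside the polygon by dart-throwing with rejection, keeping
    every accepted point at least ``min_spacing`` from all others.  When a
    ``scene`` is supplied, points are additionally restricted to its wet
    cells (patch buffers can overhang the dry channel margin).  Raises
    :class:`CapacityError` naming the patch if a point cannot be placed.
    """
    rng = np.random.default_rng(seed)
    wet = scene.wet_mask() if scene is not None else None
    accepted: list[tuple[float, float]] = []
    rows = []
    for i, patch in enumerate(patch_set.patches):
        n_points = patch.rounded_count
        minx, miny, maxx, maxy = patch.polygon.bounds
        for _ in range(n_points):
            for _try in range(max_rejections):
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                if not patch.polygon.covers(Point(x, y)):
                    continue
                if _too_close(x, y, accepted, min_spacing):
                    continue
                if wet is not None:
                    try:
                        r, c = scene.grid.cell_of(x, y)
                    except ValueError:
                        continue
                    if not wet[r, c]:
                        continue
                accepted.append((x, y))
                rows.append({"x": x, "y": y, "label": PRESENCE, "patch": i})
                break
            else:
                raise CapacityError(
                    f"patch {i} cannot hold {n_points} presences at "
                    f"{min_spacing} m spacing")
    return pd.DataFrame(rows, columns=["x", "y", "label", "patch"])


def draw_absences(scene: SpringbrookScene, patch_set: PatchSet, n_absence: int,
                  seed: int = 0, min_spacing: float = MIN_SPACING,
                  existing_points: pd.DataFrame | None = None,
                  max_rejections: int = 10_000) -> pd.DataFrame:
    """Background pseudo-absences on wet cells outside every patch polygon.

    Points are placed by seeded dart-throwing on random wet cells with a
    uniform jitter inside the cell, rejected when inside any patch or
    closer than ``min_spacing`` to any accepted point (including
    ``existing_points``, normally the presences).  Raises
    :class:`CapacityError` with the achievable maximum when the wetted
    area outside the patches cannot hold the request.
    """
    if n_absence < 0:
        raise ValueError("n_absence must be non-negative")
    rng = np.random.default_rng(seed)
    wet = scene.wet_mask()
    rows_idx, cols_idx = np.nonzero(wet)
    if len(rows_idx) == 0:
        raise ValueError("scene has no wet cells")
    union = patch_set.union()
    half = scene.grid.cell_size / 2.0

    accepted: list[tuple[float, float]] = []
    if existing_points is not None and len(existing_points):
        accepted = list(zip(existing_points["x"], existing_points["y"]))
    n_existing = len(accepted)

    rows = []
    rejections = 0
    while len(rows) < n_absence:
        k = rng.integers(len(rows_idx))
        cx, cy = scene.grid.cell_center(rows_idx[k], cols_idx[k])
        x = cx + rng.uniform(-half, half)
        y = cy + rng.uniform(-half, half)
        if union.covers(Point(x, y)) or _too_close(x, y, accepted, min_spacing):
            rejections += 1
            if rejections > max_rejections:
                raise CapacityError(
                    f"could only place {len(rows)} of {n_absence} absences at "
                    f"{min_spacing} m spacing")
            continue
        rejections = 0
        accepted.append((x, y))
        rows.append({"x": x, "y": y, "label": ABSENCE, "patch": -1})
    return pd.DataFrame(rows, columns=["x", "y", "label", "patch"])


@dataclass
class SampleSet:
    """Labelled sample points with their extracted covariates."""

    table: pd.DataFrame  # columns: x, y, label, plus one column per variable

    @property
    def n_presence(self) -> int:
        return int((self.table["label"] == PRESENCE).sum())

    @property
    def n_absence(self) -> int:
        return int((self.table["label"] == ABSENCE).sum())

    @property
    def labels(self) -> np.ndarray:
        return (self.table["label"] == PRESENCE).to_numpy(dtype=float)

    def covariates(self) -> pd.DataFrame:
        drop = [c for c in ("x", "y", "label", "patch") if c in self.table.columns]
        return self.table.drop(columns=drop)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSet":
        return cls(pd.read_csv(path))


def extract_covariates(points: pd.DataFrame, scene: SpringbrookScene,
                       variables: tuple[str, ...] = ("DEP", "VEL", "FRD", "SUB3", "TMP"),
                       ) -> SampleSet:
    """Attribute each point with the value of its containing cell.

    Point-to-cell mapping uses the grid's half-open cell intervals.
    Raises if any point lands on a nodata cell for any variable, listing
    the offending points.
    """
    table = points.copy().reset_index(drop=True)
    cells = [scene.grid.cell_of(x, y) for x, y in zip(table["x"], table["y"])]
    rows = np.array([rc[0] for rc in cells])
    cols = np.array([rc[1] for rc in cells])
    bad: list[int] = []
    for var in variables:
        vals = scene[var].values[rows, cols]
        table[var] = vals
        bad.extend(np.nonzero(~np.isfinite(vals))[0].tolist())
    if bad:
        offenders = table.loc[sorted(set(bad)), ["x", "y"]]
        raise ValueError(f"points on nodata cells:\n{offenders.to_string()}")
    return SampleSet(table)
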