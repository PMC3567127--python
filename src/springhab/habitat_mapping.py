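"""Spatially explicit habitat maps and their verification diagnostics.

A fitted logistic model is applied cell-by-cell to a scene's covariate
layers to give a probability surface, thresholded at a cutpoint (0.3 by
default, chosen to balance omission and commission) into a binary habitat
map.  Verification overlays independent fish locations: a fish within two
cells (~24 cm) of predicted habitat counts as correctly classified,
absorbing field positional error.  The density-by-probability-class
diagnostic checks that fish density rises across probability classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .habitat_model import FittedHabitatModel
from .raster_core import RasterLayer, SpringbrookScene

__all__ = [
    "HabitatMap",
    "DensityClassResult",
    "predict_probability",
    "binarize",
    "verify_against_points",
    "density_by_class",
]


def predict_probability(scene: SpringbrookScene, model: FittedHabitatModel) -> RasterLayer:
    """Per-wet-cell occurrence probability (PROB layer); nodata on dry cells."""
    wet = scene.wet_mask()
    missing = [t.variable for t in model.terms if t.variable not in scene]
    if missing:
        raise KeyError(f"scene lacks covariate layer(s) {missing} required by the model")
    arrays = {t.variable: scene[t.variable].values[wet] for t in model.terms}
    prob = np.full(scene.grid.shape, np.nan)
    prob[wet] = model.predict_arrays(arrays)
    return RasterLayer(scene.grid, "PROB", prob)


@dataclass
class HabitatMap:
    """Binary habitat map plus its summary statistics."""

    prob: RasterLayer
    hab: RasterLayer
    cutpoint: float
    habitat_area: float      # m^2
    habitat_fraction: float  # % of wetted (valid-probability) cells
    mean_probability: float
    max_probability: float
    min_probability: float

    def summary(self) -> dict:
        return {
            "cutpoint": self.cutpoint,
            "habitat_area_m2": self.habitat_area,
            "habitat_fraction_pct": self.habitat_fraction,
            "mean_probability": self.mean_probability,
            "max_probability": self.max_probability,
            "min_probability": self.min_probability,
        }


def binarize(prob: RasterLayer, cutpoint: float = 0.3) -> HabitatMap:
    """Threshold a probability layer: habitat where p > cutpoint (strict),
    non-habitat where p <= cutpoint."""
    valid = np.isfinite(prob.values)
    hab_vals = np.full(prob.values.shape, np.nan)
    hab_vals[valid] = (prob.values[valid] > cutpoint).astype(float)
    hab = RasterLayer(prob.grid, "HAB", hab_vals)
    n_valid = int(valid.sum())
    n_hab = int(np.nansum(hab_vals))
    p = prob.values[valid]
    return HabitatMap(
        prob=prob,
        hab=hab,
        cutpoint=cutpoint,
        habitat_area=n_hab * prob.grid.cell_area,
        habitat_fraction=100.0 * n_hab / n_valid if n_valid else 0.0,
        mean_probability=float(p.mean()) if n_valid else float("nan"),
        max_probability=float(p.max()) if n_valid else float("nan"),
        min_probability=float(p.min()) if n_valid else float("nan"),
    )


def verify_against_points(hab: RasterLayer, points: pd.DataFrame,
                          tolerance_cells: int = 2) -> float:
    """Percent of points with predicted habitat within the cell tolerance.

    A point is correct when any habitat cell lies within a Chebyshev
    distance of ``tolerance_cells`` of the point's containing cell (a
    square 2-cell buffer, ~24 cm at the default resolution).
    """
    if len(points) == 0:
        raise ValueError("no points to verify against")
    hab01 = np.where(np.isfinite(hab.values), hab.values, 0.0)
    if tolerance_cells > 0:
        near = maximum_filter(hab01, size=2 * tolerance_cells + 1, mode="constant")
    else:
        near = hab01
    correct = 0
    for x, y in zip(points["x"], points["y"]):
        row, col = hab.grid.cell_of(x, y)
        if near[row, col] > 0:
            correct += 1
    return 100.0 * correct / len(points)


@dataclass
class DensityClassResult:
    """Fish density per probability class and its linear trend."""

    bins: list[tuple[float, float]]   # percent-probability intervals (lo, hi]
    cell_counts: list[int]
    fish_counts: list[int]
    densities: list[float]            # fish per cell
    slope: float                      # OLS slope of density vs class index
    intercept: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": range(1, len(self.bins) + 1),
            "prob_low_pct": [b[0] for b in self.bins],
            "prob_high_pct": [b[1] for b in self.bins],
            "cells": self.cell_counts,
            "fish": self.fish_counts,
            "density": self.densities,
        })


def density_by_class(prob: RasterLayer, points: pd.DataFrame,
                     bin_width: float = 20.0,
                     merge_sparse_top: bool = True,
                     min_cells: int = 5) -> DensityClassResult:
    """Fish density inside probability classes, with sparse top bins merged.

    Classes are half-open intervals of percent probability (0-20,
    20.1-40, ...); the first class includes 0.  Top classes are merged
    downward while they hold fewer than ``min_cells`` cells or less than
    one expected fish (the total fish count times the class's share of
    cells), mirroring the merge of the two uppermost classes when model
    probabilities top out in the 80s.  An ordinary least-squares line is
    fitted through (class index, density).
    """
    valid = np.isfinite(prob.values)
    if not valid.any():
        raise ValueError("probability layer has no wet cells")
    if len(points) == 0:
        raise ValueError("no fish points supplied")

    pct = prob.values[valid] * 100.0
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    edges[-1] = max(edges[-1], 100.0)
    n_bins = len(edges) - 1
    # class k (0-based) is (edges[k], edges[k+1]]; class 0 includes 0
    cell_class = np.clip(np.searchsorted(edges, pct, side="left") - 1, 0, n_bins - 1)
    cell_counts = np.bincount(cell_class, minlength=n_bins)

    fish_class = []
    for x, y in zip(points["x"], points["y"]):
        row, col = prob.grid.cell_of(x, y)
        p = prob.values[row, col]
        if np.isfinite(p):
            k = int(np.clip(np.searchsorted(edges, p * 100.0, side="left") - 1,
                            0, n_bins - 1))
            fish_class.append(k)
    fish_counts = np.bincount(np.asarray(fish_class, dtype=int), minlength=n_bins)

    bins = [(float(edges[k]), float(edges[k + 1])) for k in range(n_bins)]
    cells = cell_counts.astype(int).tolist()
    fish = fish_counts.astype(int).tolist()

    if merge_sparse_top:
        total_fish = sum(fish)
        total_cells = sum(cells)
        while len(cells) > 1:
            expected = total_fish * cells[-1] / total_cells if total_cells else 0.0
            if cells[-1] < min_cells or expected < 1.0:
                cells[-2] += cells[-1]
                fish[-2] += fish[-1]
                bins[-2] = (bins[-2][0], bins[-1][1])
                del cells[-1], fish[-1], bins[-1]
            else:
                break

    densities = [f / c if c else 0.0 for f, c in zip(fish, cells)]
    idx = np.arange(1, len(densities) + 1, dtype=float)
    if len(densities) >= 2:
        slope, intercept = np.polyfit(idx, densities, 1)
    else:
        slope, intercept = 0.0, densities[0] if densities else 0.0
    return DensityClassResult(bins, cells, fish, densities,
                              float(slope), float(intercept))
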