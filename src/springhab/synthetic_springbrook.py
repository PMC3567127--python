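"""Synthetic springbrook generator.

Emulates a small (~130 m) spring-fed desert channel at 12 x 12 cm raster
resolution: an alternating narrow/wide planform forces riffle and pool
structure, a per-cross-section Manning stage solver produces co-registered
depth and velocity grids at any discharge, substrate is laid down as
contiguous patches of fines/gravels/cobble-boulder, temperature is
near-constant at the spring temperature (~31 deg C), and fish observations
are simulated from a known logistic habitat model so that every downstream
stage (sampling, fitting, mapping, flow response) can be exercised and its
parameter recovery verified.

The hydraulics are deliberately one-dimensional per cross-section: at each
station the water-surface stage is found such that the Manning conveyance
discharge equals the target Q, and the discharge is distributed laterally
in proportion to each cell's conveyance (d^(5/3)), which makes the
cross-section discharge audit Sum(v*d*dx) = Q hold by construction.  This
is a mass-conserving stand-in for a 2-D depth-averaged momentum solver,
not a replacement for one.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, asdict, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import uniform_filter

from .raster_core import (
    GridSpec,
    RasterLayer,
    SpringbrookScene,
    assemble_scene,
    DRY_THRESHOLD,
)
from .hydraulics import compute_froude
from .habitat_model import FittedHabitatModel

__all__ = [
    "ChannelTemplate",
    "generate_bathymetry",
    "solve_hydraulics",
    "solve_section",
    "generate_substrate",
    "aggregate_substrate",
    "simulate_observations",
    "build_scene",
    "HydraulicsError",
]


class HydraulicsError(RuntimeError):
    """Stage search failed to converge at some cross-section."""


@dataclass(frozen=True)
class ChannelTemplate:
    """Parameters of the synthetic channel.

    Geometry: channel width oscillates between ``width_min`` and
    ``width_max`` with period ``unit_wavelength``; ``pool_bias`` > 1 skews
    the profile toward narrow (riffle) stations, < 1 toward wide (pool)
    ones.  The local energy slope is log-interpolated between
    ``slope_pool`` (wide, deep, slow - a near-flat backwater) and
    ``slope_riffle`` (narrow, shallow, fast), which at the default
    baseflow of 0.071 cms gives thalweg pool depths in the 0.6-0.7 m
    range that dace prefer and a pool-dominated unit mix with all three
    channel units represented.
    """

    name: str = "synthetic-springbrook"
    length: float = 130.0
    cell_size: float = 0.12
    baseflow_q: float = 0.071
    width_min: float = 1.5
    width_max: float = 3.2
    unit_wavelength: float = 14.0
    pool_bias: float = 1.6
    slope_pool: float = 5.0e-6
    slope_riffle: float = 1.2e-2
    manning_n: float = 0.035
    bank_relief: float = 0.35
    pool_depth_boost: float = 0.45
    bed_noise: float = 0.01
    substrate_mix: tuple[float, float, float] = (0.2, 0.4, 0.4)
    mean_patch_area: float = 1.0
    spring_temperature: float = 31.0
    cooling_rate: float = 0.0  # deg C per metre downstream
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.length, self.width_min, self.width_max, self.manning_n,
               self.slope_pool, self.slope_riffle, self.cell_size) <= 0:
            raise ValueError("length, widths, slopes, manning_n, cell_size must be positive")
        if self.width_min < 3 * self.cell_size:
            raise ValueError("width_min too narrow for the grid resolution")
        if self.width_max < self.width_min:
            raise ValueError("width_max must be >= width_min")
        if not math.isclose(sum(self.substrate_mix), 1.0, abs_tol=1e-6):
            raise ValueError("substrate_mix must sum to 1")

    # -- geometry profiles -------------------------------------------------

    @property
    def n_cols(self) -> int:
        return int(round(self.length / self.cell_size))

    @property
    def n_rows(self) -> int:
        return int(math.ceil(self.width_max / self.cell_size)) + 4

    def grid(self) -> GridSpec:
        return GridSpec(origin_x=0.0, origin_y=0.0, n_rows=self.n_rows,
                        n_cols=self.n_cols, cell_size=self.cell_size,
                        crs_label="local planar (synthetic)")

    def stations(self) -> np.ndarray:
        """Streamwise coordinates of column centres (m)."""
        return (np.arange(self.n_cols) + 0.5) * self.cell_size

    def width_profile(self) -> np.ndarray:
        x = self.stations()
        s = 0.5 * (1.0 + np.sin(2.0 * np.pi * x / self.unit_wavelength))
        return self.width_min + (self.width_max - self.width_min) * s**self.pool_bias

    def slope_profile(self) -> np.ndarray:
        w = self.width_profile()
        frac = (w - self.width_min) / max(self.width_max - self.width_min, 1e-12)
        log_s = (np.log(self.slope_riffle) * (1.0 - frac) + np.log(self.slope_pool) * frac)
        return np.exp(log_s)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["substrate_mix"] = list(self.substrate_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelTemplate":
        d = dict(d)
        if "substrate_mix" in d:
            d["substrate_mix"] = tuple(d["substrate_mix"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ChannelTemplate":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def generate_bathymetry(template: ChannelTemplate) -> RasterLayer:
    """Bed-elevation layer (BED, m); NaN outside the channel planform.

    The thalweg falls with the local energy slope, wide stations are
    lowered by the pool-depth boost, and each cross-section is parabolic
    from thalweg to bank top (``bank_relief``).  A seeded, smoothed noise
    field adds bed roughness; output is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([template.seed, 0]))
    grid = template.grid()
    widths = template.width_profile()
    slopes = template.slope_profile()
    frac = (widths - template.width_min) / max(template.width_max - template.width_min, 1e-12)

    thalweg = -np.cumsum(slopes) * template.cell_size
    thalweg = thalweg - template.pool_depth_boost * frac**2

    # cross-stream coordinates of row centres, measured from the channel axis
    center = grid.n_rows / 2.0
    offsets = (np.arange(grid.n_rows) + 0.5 - center) * template.cell_size

    bed = np.full(grid.shape, np.nan)
    half_w = widths / 2.0
    for j in range(grid.n_cols):
        inside = np.abs(offsets) <= half_w[j]
        shape = (np.abs(offsets[inside]) / half_w[j]) ** 2
        bed[inside, j] = thalweg[j] + template.bank_relief * shape

    if template.bed_noise > 0:
        noise = rng.normal(0.0, 1.0, size=grid.shape)
        noise = uniform_filter(noise, size=7, mode="nearest")
        noise *= template.bed_noise / max(noise.std(), 1e-12)
        bed = np.where(np.isfinite(bed), bed + noise, np.nan)
    return RasterLayer(grid, "BED", bed)


def solve_section(bed: np.ndarray, q: float, slope: float, manning_n: float,
                  cell_size: float, tol: float = 0.01, max_iter: int = 100):
    """Solve one cross-section for stage, depth and velocity.

    Finds the water-surface elevation h by bisection such that the Manning
    conveyance discharge Sum((1/n) d^(5/3) sqrt(S) dx) equals ``q`` to
    within ``tol * q``, then allocates the discharge laterally in
    proportion to cell conveyance so that Sum(v*d*dx) = q exactly.
    Returns (depths, velocities) for the section's cells.
    """
    bed = np.asarray(bed, dtype=float)
    if q <= 0:
        return np.zeros_like(bed), np.zeros_like(bed)
    k = math.sqrt(slope) / manning_n

    def conveyance_q(h: float) -> float:
        d = np.clip(h - bed, 0.0, None)
        return float(k * np.sum(d ** (5.0 / 3.0)) * cell_size)

    lo = float(bed.min())
    hi = lo + 0.05
    for _ in range(60):
        if conveyance_q(hi) >= q:
            break
        hi = lo + (hi - lo) * 2.0
    else:
        raise HydraulicsError("stage search failed to bracket the discharge")
    h = hi
    for _ in range(max_iter):
        h = 0.5 * (lo + hi)
        qh = conveyance_q(h)
        if abs(qh - q) <= tol * q:
            break
        if qh < q:
            lo = h
        else:
            hi = h
    else:
        raise HydraulicsError("stage bisection did not converge")

    d = np.clip(h - bed, 0.0, None)
    total_conveyance = np.sum(d ** (5.0 / 3.0)) * cell_size
    v = np.where(d > 0, q * d ** (2.0 / 3.0) / total_conveyance, 0.0)
    return d, v


def solve_hydraulics(template: ChannelTemplate, q: float,
                     bed: RasterLayer | None = None) -> tuple[RasterLayer, RasterLayer]:
    """Depth (DEP) and velocity (VEL) layers at discharge ``q`` (cms).

    Every cross-section satisfies the mass-conservation audit
    |Sum(v*d*dx) - q| / q <= 0.01.  ``q = 0`` yields the dry state.
    """
    if q < 0:
        raise ValueError("discharge must be non-negative")
    if bed is None:
        bed = generate_bathymetry(template)
    slopes = template.slope_profile()
    dep = np.full(bed.grid.shape, np.nan)
    vel = np.full(bed.grid.shape, np.nan)
    for j in range(bed.grid.n_cols):
        col = bed.values[:, j]
        inside = np.isfinite(col)
        if not inside.any():
            continue
        try:
            d, v = solve_section(col[inside], q, slopes[j], template.manning_n,
                                 template.cell_size)
        except HydraulicsError as exc:
            raise HydraulicsError(f"section {j}: {exc}") from exc
        dep[inside, j] = d
        vel[inside, j] = v
    return (RasterLayer(bed.grid, "DEP", dep), RasterLayer(bed.grid, "VEL", vel))


# ---------------------------------------------------------------------------
# Substrate

#: SUB7 -> SUB3 aggregation: class 1 is fines, 2-4 the gravel sizes,
#: 5-7 cobble through boulder.
_SUB7_TO_SUB3 = {1: 1, 2: 2, 3: 2, 4: 2, 5: 3, 6: 3, 7: 3}
_SUB3_TO_SUB7 = {1: (1,), 2: (2, 3, 4), 3: (5, 6, 7)}


def aggregate_substrate(sub7: np.ndarray) -> np.ndarray:
    """Aggregate 7-class substrate codes into the 3-class grouping."""
    out = np.full(np.shape(sub7), np.nan)
    for k7, k3 in _SUB7_TO_SUB3.items():
        out[np.asarray(sub7) == k7] = k3
    return out


def generate_substrate(template: ChannelTemplate,
                       bed: RasterLayer | None = None) -> tuple[RasterLayer, RasterLayer]:
    """Contiguous substrate patches as (SUB3, SUB7) layers.

    Seeded competitive region growing: patch seeds are allocated to the
    three substrate groups in proportion to ``substrate_mix`` and grown
    cell by cell, always expanding the group furthest below its target
    share, so empirical class shares track the mix closely while patches
    stay contiguous.  Mean patch area is ``mean_patch_area`` m^2.
    """
    rng = np.random.default_rng(np.random.SeedSequence([template.seed, 1]))
    if bed is None:
        bed = generate_bathymetry(template)
    mask = np.isfinite(bed.values)
    cells = np.argwhere(mask)
    n_cells = len(cells)
    patch_cells = max(int(template.mean_patch_area / bed.grid.cell_area), 4)
    n_seeds = max(len(template.substrate_mix), n_cells // patch_cells)

    mix = np.asarray(template.substrate_mix, dtype=float)
    # largest-remainder allocation of seeds to the three groups
    raw = mix * n_seeds
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_seeds - counts.sum()]:
        counts[i] += 1

    sub7 = np.full(bed.grid.shape, np.nan)
    assigned = np.zeros(3, dtype=int)
    frontiers: list[list] = [[], [], []]  # per group: heap of (priority, r, c, code7)
    n_assigned = 0

    def spawn(group: int) -> None:
        unfilled = cells[np.isnan(sub7[cells[:, 0], cells[:, 1]])]
        if len(unfilled) == 0:
            return
        r, c = unfilled[rng.integers(len(unfilled))]
        code7 = int(rng.choice(_SUB3_TO_SUB7[group + 1]))
        heapq.heappush(frontiers[group], (rng.random(), int(r), int(c), code7))

    for group, k in enumerate(counts):
        for _ in range(max(int(k), 1)):
            spawn(group)

    shape = bed.grid.shape
    while n_assigned < n_cells:
        deficit = mix - (assigned / max(n_assigned, 1))
        order = np.argsort(deficit)[::-1]
        group = next((g for g in order if mix[g] > 0), int(order[0]))
        if not frontiers[group]:
            spawn(group)
            if not frontiers[group]:  # no unassigned cells left for this group
                group = next((g for g in order if frontiers[g]), None)
                if group is None:
                    break
        _, r, c, code7 = heapq.heappop(frontiers[group])
        if not np.isnan(sub7[r, c]):
            continue
        sub7[r, c] = code7
        assigned[group] += 1
        n_assigned += 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < shape[0] and 0 <= cc < shape[1] and mask[rr, cc] \
                    and np.isnan(sub7[rr, cc]):
                heapq.heappush(frontiers[group], (rng.random(), rr, cc, code7))

    sub3 = aggregate_substrate(sub7)
    return (RasterLayer(bed.grid, "SUB3", sub3), RasterLayer(bed.grid, "SUB7", sub7))


# ---------------------------------------------------------------------------
# Temperature and scene assembly


def generate_temperature(template: ChannelTemplate,
                         bed: RasterLayer | None = None) -> RasterLayer:
    """Temperature layer: spring temperature with optional downstream cooling."""
    if bed is None:
        bed = generate_bathymetry(template)
    x = template.stations()
    tmp = np.where(np.isfinite(bed.values),
                   template.spring_temperature - template.cooling_rate * x[None, :],
                   np.nan)
    return RasterLayer(bed.grid, "TMP", tmp)


def build_scene(template: ChannelTemplate, q: float | None = None,
                is_baseflow: bool | None = None) -> SpringbrookScene:
    """Full co-registered scene (BED, DEP, VEL, FRD, SUB3, SUB7, TMP) at ``q``.

    Substrate, temperature and geometry depend only on the template seed,
    so scenes at different discharges share everything but hydraulics.
    """
    if q is None:
        q = template.baseflow_q
    bed = generate_bathymetry(template)
    dep, vel = solve_hydraulics(template, q, bed=bed)
    frd = compute_froude(dep, vel)
    sub3, sub7 = generate_substrate(template, bed=bed)
    tmp = generate_temperature(template, bed=bed)
    if is_baseflow is None:
        is_baseflow = math.isclose(q, template.baseflow_q, rel_tol=1e-9)
    return assemble_scene([bed, dep, vel, frd, sub3, sub7, tmp],
                          q=q, length=template.length, name=template.name,
                          is_baseflow=is_baseflow)


# ---------------------------------------------------------------------------
# Simulated fish observations


def simulate_observations(scene: SpringbrookScene, true_model: FittedHabitatModel,
                          n_fish: int = 141, seed: int = 0, n_surveys: int = 3,
                          patch_spread: float = 1.0,
                          fish_per_patch: int = 8) -> pd.DataFrame:
    """Simulate patchily distributed fish from a known habitat model.

    Patch centres are drawn from wet cells with probability proportional
    to the model's per-cell occurrence probability; each survey allocates
    ``n_fish`` fish across patches (at least one per patch) and places
    each fish on a probability-weighted wet cell within ``patch_spread``
    metres of its patch centre.  Returns a point table with columns
    x, y, survey, count.
    """
    wet = scene.wet_mask()
    rows, cols = np.nonzero(wet)
    n_wet = len(rows)
    if n_fish > n_wet:
        raise ValueError(f"n_fish={n_fish} exceeds {n_wet} wet cells")
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")

    arrays = {t.variable: scene[t.variable].values[wet] for t in true_model.terms}
    p = true_model.predict_arrays(arrays)
    weights = p / p.sum()

    rng = np.random.default_rng(seed)
    n_patches = max(1, min(n_fish, n_fish // fish_per_patch or 1))
    centre_idx = rng.choice(n_wet, size=n_patches, replace=False, p=weights)

    radius = max(int(round(patch_spread / scene.grid.cell_size)), 1)
    # candidate cells per patch: wet cells within a square neighbourhood
    candidates = []
    for ci in centre_idx:
        r0, c0 = rows[ci], cols[ci]
        near = np.nonzero((np.abs(rows - r0) <= radius) & (np.abs(cols - c0) <= radius))[0]
        candidates.append(near)

    patch_w = p[centre_idx] / p[centre_idx].sum()
    records = []
    jitter = 0.4 * scene.grid.cell_size
    for survey in range(1, n_surveys + 1):
        alloc = np.ones(n_patches, dtype=int)
        extra = n_fish - n_patches
        if extra > 0:
            alloc += rng.multinomial(extra, patch_w)
        for k in range(n_patches):
            near = candidates[k]
            w = p[near] / p[near].sum()
            chosen = rng.choice(near, size=alloc[k], replace=True, p=w)
            for idx in chosen:
                x, y = scene.grid.cell_center(rows[idx], cols[idx])
                records.append({
                    "x": x + rng.uniform(-jitter, jitter),
                    "y": y + rng.uniform(-jitter, jitter),
                    "survey": f"survey_{survey}",
                    "count": 1,
                })
    return pd.DataFrame(records)
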