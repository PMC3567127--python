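"""Derived hydraulic quantities: Froude number and channel-unit structure.

The Froude number Fr = V / sqrt(g d) discriminates channel units
objectively: slow deep pools (low Fr), fast shallow riffles (high Fr),
and intermediate glides.  Fr < 1 is subcritical flow, Fr > 1
supercritical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_core import (
    DRY_THRESHOLD,
    RasterLayer,
    RasterValidationError,
    CoRegistrationError,
    UNIT_CODES,
)

__all__ = [
    "GRAVITY",
    "FroudeThresholds",
    "UnitComposition",
    "compute_froude",
    "classify_channel_units",
    "unit_composition",
]

GRAVITY = 9.81  # m/s^2, fixed


@dataclass(frozen=True)
class FroudeThresholds:
    """Channel-unit thresholds: pool below ``pool_max``, riffle above
    ``riffle_min``, glide in between (boundary values inclusive of glide)."""

    pool_max: float = 0.18
    riffle_min: float = 0.41

    def __post_init__(self) -> None:
        if not 0 < self.pool_max < self.riffle_min:
            raise ValueError("need 0 < pool_max < riffle_min")


@dataclass(frozen=True)
class UnitComposition:
    """Percent of wet cells in each channel unit; sums to 100."""

    percent_pool: float
    percent_glide: float
    percent_riffle: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.percent_pool, self.percent_glide, self.percent_riffle)

    def to_row(self, scene_name: str = "", q: float = float("nan")) -> pd.DataFrame:
        return pd.DataFrame([{
            "scene": scene_name, "q_cms": q,
            "pct_pool": self.percent_pool,
            "pct_glide": self.percent_glide,
            "pct_riffle": self.percent_riffle,
        }])


def compute_froude(dep: RasterLayer, vel: RasterLayer,
                   dry_threshold: float = DRY_THRESHOLD) -> RasterLayer:
    """Froude layer Fr = V / sqrt(g d) on wet cells; nodata elsewhere.

    Cells shallower than ``dry_threshold`` get nodata rather than an
    unstable near-division-by-zero value.
    """
    if not dep.grid.same_grid(vel.grid):
        raise CoRegistrationError("DEP and VEL layers are not co-registered")
    d = dep.values
    v = vel.values
    if np.any(d[np.isfinite(d)] < 0):
        raise RasterValidationError("negative depths")
    wet = np.isfinite(d) & np.isfinite(v) & (d > dry_threshold)
    frd = np.full(d.shape, np.nan)
    frd[wet] = v[wet] / np.sqrt(GRAVITY * d[wet])
    return RasterLayer(dep.grid, "FRD", frd)


def classify_channel_units(frd: RasterLayer,
                           thresholds: FroudeThresholds = FroudeThresholds()) -> RasterLayer:
    """UNIT layer: pool where Fr < pool_max, riffle where Fr > riffle_min,
    glide otherwise (values exactly at a threshold are glide)."""
    fr = frd.values
    unit = np.full(fr.shape, np.nan)
    valid = np.isfinite(fr)
    unit[valid] = UNIT_CODES["glide"]
    unit[valid & (fr < thresholds.pool_max)] = UNIT_CODES["pool"]
    unit[valid & (fr > thresholds.riffle_min)] = UNIT_CODES["riffle"]
    return RasterLayer(frd.grid, "UNIT", unit)


def unit_composition(unit_layer: RasterLayer) -> UnitComposition:
    """Percent pool/glide/riffle over classified (wet) cells."""
    vals = unit_layer.values
    valid = np.isfinite(vals)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no classified cells in UNIT layer")
    pct = {name: 100.0 * float(np.sum(vals[valid] == code)) / n
           for name, code in UNIT_CODES.items()}
    return UnitComposition(pct["pool"], pct["glide"], pct["riffle"])
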