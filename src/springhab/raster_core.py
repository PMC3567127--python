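"""Grid data model, co-registration rules, and raster/point I/O.

All downstream stages (hydraulics, sampling, modelling, mapping) operate on
co-registered single-band rasters at a shared fine resolution (default
12 x 12 cm, i.e. 0.0144 m^2 cells).  The grid is a plain planar grid: cell
centres, row 0 northernmost, half-open cell intervals for point-in-cell
tests.  Nodata (dry or outside-channel cells) is IEEE NaN in memory and
-9999 in ESRI ASCII grids on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "RasterLayer",
    "SpringbrookScene",
    "RasterFormatError",
    "RasterValidationError",
    "CoRegistrationError",
    "VARIABLE_TAGS",
    "DRY_THRESHOLD",
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
    "assemble_scene",
    "wetted_area",
]

#: Depth (m) above which a cell counts as wet.
DRY_THRESHOLD = 0.001

NODATA_ON_DISK = -9999.0

#: Recognised layer variables.  DEP/VEL in SI units, FRD dimensionless,
#: SUB3/SUB7 categorical substrate codes, TMP in deg C, PROB a model
#: probability, HAB a binary habitat indicator, UNIT a channel-unit code.
VARIABLE_TAGS = ("DEP", "VEL", "FRD", "SUB3", "SUB7", "TMP", "PROB", "HAB", "UNIT", "BED")

#: Integer codes used for the UNIT (channel-unit) layer.
UNIT_CODES = {"pool": 1, "glide": 2, "riffle": 3}
UNIT_NAMES = {v: k for k, v in UNIT_CODES.items()}


class RasterFormatError(ValueError):
    """Malformed raster file (bad header, short rows, ...)."""


class RasterValidationError(ValueError):
    """Layer values violate the domain of their variable tag."""


class CoRegistrationError(ValueError):
    """Layers in a scene do not share an identical grid."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular planar grid.

    ``origin_x``/``origin_y`` are the coordinates of the *lower-left corner*
    of the grid (ESRI xllcorner/yllcorner convention).  Row 0 is the
    northernmost row.  ``crs_label`` is an opaque label (e.g. ``"UTM Zone 11
    NAD83"``); the package never reprojects.
    """

    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    cell_size: float = 0.12
    crs_label: str = ""

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def cell_area(self) -> float:
        """Area of one cell in m^2 (0.0144 at the default 0.12 m size)."""
        return self.cell_size**2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its (row, col); half-open cell intervals.

        A point lying exactly on the shared edge of two cells belongs to the
        cell with the larger x (or larger y, i.e. smaller row index).
        """
        col = math.floor((x - self.origin_x) / self.cell_size)
        row_from_bottom = math.floor((y - self.origin_y) / self.cell_size)
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def same_grid(self, other: "GridSpec") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9)
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-6)
        )


def _validate_values(tag: str, values: np.ndarray) -> None:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return
    if tag in ("DEP", "VEL", "FRD") and np.any(finite < 0):
        raise RasterValidationError(f"{tag} must be non-negative on wet cells")
    if tag == "SUB3" and not np.all(np.isin(finite, [1, 2, 3])):
        bad = sorted(set(finite[~np.isin(finite, [1, 2, 3])]))
        raise RasterValidationError(f"SUB3 values must be in {{1,2,3}}; found {bad}")
    if tag == "SUB7" and not np.all(np.isin(finite, range(1, 8))):
        bad = sorted(set(finite[~np.isin(finite, range(1, 8))]))
        raise RasterValidationError(f"SUB7 values must be in {{1..7}}; found {bad}")
    if tag == "PROB" and (np.any(finite < 0) or np.any(finite > 1)):
        raise RasterValidationError("PROB values must lie in [0, 1]")
    if tag == "HAB" and not np.all(np.isin(finite, [0, 1])):
        raise RasterValidationError("HAB values must be 0 or 1")
    if tag == "UNIT" and not np.all(np.isin(finite, list(UNIT_CODES.values()))):
        raise RasterValidationError("UNIT values must be pool/glide/riffle codes 1/2/3")


@dataclass
class RasterLayer:
    """One gridded variable on a :class:`GridSpec`; NaN marks nodata."""

    grid: GridSpec
    variable_tag: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.variable_tag not in VARIABLE_TAGS:
            raise RasterValidationError(f"unknown variable tag {self.variable_tag!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise CoRegistrationError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        _validate_values(self.variable_tag, self.values)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return np.isfinite(self.values)

    def value_at(self, x: float, y: float) -> float:
        row, col = self.grid.cell_of(x, y)
        return float(self.values[row, col])

    def with_values(self, values: np.ndarray, tag: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, tag or self.variable_tag, values)


@dataclass
class SpringbrookScene:
    """Co-registered layers for one springbrook at one discharge."""

    name: str
    discharge_q: float
    channel_length: float
    layers: dict[str, RasterLayer]
    is_baseflow: bool = True

    def __post_init__(self) -> None:
        if self.discharge_q <= 0:
            raise ValueError("discharge_q must be positive")
        if not self.layers:
            raise ValueError("scene needs at least one layer")
        ref = next(iter(self.layers.values())).grid
        for tag, layer in self.layers.items():
            if layer.variable_tag != tag:
                raise ValueError(f"layer stored under {tag!r} is tagged {layer.variable_tag!r}")
            if not layer.grid.same_grid(ref):
                raise CoRegistrationError(f"layer {tag} is not co-registered with the scene grid")

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.layers.values())).grid

    def __getitem__(self, tag: str) -> RasterLayer:
        try:
            return self.layers[tag]
        except KeyError:
            raise KeyError(f"scene {self.name!r} has no {tag} layer") from None

    def __contains__(self, tag: str) -> bool:
        return tag in self.layers

    def wet_mask(self, dry_threshold: float = DRY_THRESHOLD) -> np.ndarray:
        dep = self["DEP"]
        return np.isfinite(dep.values) & (dep.values > dry_threshold)

    def with_layers(self, **layers: RasterLayer) -> "SpringbrookScene":
        merged = dict(self.layers)
        merged.update(layers)
        return replace(self, layers=merged)


def assemble_scene(
    layers,
    q: float,
    length: float,
    name: str = "springbrook",
    is_baseflow: bool = True,
) -> SpringbrookScene:
    """Bundle layers into a scene, verifying co-registration and tag uniqueness."""
    by_tag: dict[str, RasterLayer] = {}
    for layer in layers:
        if layer.variable_tag in by_tag:
            raise ValueError(f"duplicate layer for tag {layer.variable_tag}")
        by_tag[layer.variable_tag] = layer
    return SpringbrookScene(
        name=name, discharge_q=q, channel_length=length, layers=by_tag, is_baseflow=is_baseflow
    )


def wetted_area(scene: SpringbrookScene, dry_threshold: float = DRY_THRESHOLD) -> float:
    """Wetted area in m^2: count of wet cells times cell area."""
    if "DEP" not in scene:
        raise KeyError("wetted_area requires a DEP layer")
    return int(scene.wet_mask(dry_threshold).sum()) * scene.grid.cell_area


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_raster(layer: RasterLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid (-9999 nodata)."""
    g = layer.grid
    vals = np.where(np.isfinite(layer.values), layer.values, NODATA_ON_DISK)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_x:.6f}\n")
        fh.write(f"yllcorner {g.origin_y:.6f}\n")
        fh.write(f"cellsize {g.cell_size:.6f}\n")
        fh.write(f"NODATA_value {NODATA_ON_DISK:.0f}\n")
        np.savetxt(fh, vals, fmt="%.8g")


def read_raster(path, variable_tag: str, crs_label: str = "") -> RasterLayer:
    """Read an ESRI ASCII grid as a layer of the given variable.

    Raises :class:`RasterFormatError` for a malformed header and
    :class:`RasterValidationError` when values violate the tag's domain.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(f"bad header line {line!r}") from exc
            n_header += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise RasterFormatError(f"missing header keys {missing} in {path}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    try:
        values = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"malformed data block in {path}") from exc
    if values.shape != (n_rows, n_cols):
        raise RasterFormatError(
            f"data block shape {values.shape} does not match header ({n_rows}, {n_cols})"
        )
    nodata = header.get("nodata_value", NODATA_ON_DISK)
    values = np.where(values == nodata, np.nan, values)
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        crs_label=crs_label,
    )
    return RasterLayer(grid, variable_tag, values)


# ---------------------------------------------------------------------------
# Point-table I/O (CSV with columns x, y, label, count)


def write_points(points: pd.DataFrame, path) -> None:
    points.to_csv(path, index=False)


def read_points(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"point table {path} lacks required column {col!r}")
    return df
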