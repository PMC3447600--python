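"""Lattice data types, class scheme, raster/table I/O and driver normalization.

The simulator operates on square-celled categorical rasters (land-use class
codes) and aligned continuous covariate rasters ("drivers") scaled to [0, 1].
The mandatory on-disk dialect is ESRI ASCII Grid, which keeps fixtures
human-readable and diff-able; codes round-trip bit-exactly.

Conventions: row 0 is the northernmost row; all indexing is 0-based
(row, col); cell areas are reported in km².
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClassScheme",
    "LandUseGrid",
    "DriverStack",
    "DEFAULT_SCHEME",
    "DRIVER_NAMES",
    "read_landuse_raster",
    "write_landuse_raster",
    "read_float_raster",
    "write_float_raster",
    "normalize_driver",
    "area_table",
]

#: Canonical driver layer names (distance covariates, terrain, socio-economic).
DRIVER_NAMES = (
    "dist_town",
    "dist_highway",
    "dist_river",
    "dem",
    "slope",
    "gdp_pc",
    "pop_density",
)


@dataclass(frozen=True)
class ClassScheme:
    """Land-use classification: four classes, optional subclass codes, nodata.

    Parameters
    ----------
    classes
        Mapping of class name -> integer code. Codes must be unique and
        distinct from ``nodata``.
    subclasses
        Optional mapping of subclass code -> class name (e.g. paddy field and
        dry field both mapping to cultivated land).
    nodata
        Integer code marking cells outside the study area.
    """

    classes: dict = field(
        default_factory=lambda: {
            "cultivated": 1,
            "ecological": 2,
            "construction": 3,
            "other": 4,
        }
    )
    subclasses: dict = field(default_factory=dict)
    nodata: int = -9999

    def __post_init__(self):
        codes = list(self.classes.values())
        if len(set(codes)) != len(codes):
            raise ValueError("class codes must be unique")
        if self.nodata in codes:
            raise ValueError("nodata code collides with a class code")
        for sub, cls in self.subclasses.items():
            if cls not in self.classes:
                raise ValueError(f"subclass {sub} maps to unknown class {cls!r}")

    @property
    def codes(self) -> tuple:
        return tuple(self.classes.values())

    @property
    def names(self) -> tuple:
        return tuple(self.classes.keys())

    def code(self, name: str) -> int:
        return self.classes[name]

    def name(self, code: int) -> str:
        for n, c in self.classes.items():
            if c == code:
                return n
        raise KeyError(code)

    def to_class_code(self, subclass_code: int) -> int:
        """Map a subclass code onto its class code (class codes pass through)."""
        if subclass_code in self.codes:
            return subclass_code
        if subclass_code in self.subclasses:
            return self.classes[self.subclasses[subclass_code]]
        raise KeyError(f"unknown class code {subclass_code}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "classes": dict(self.classes),
                    "subclasses": {int(k): v for k, v in self.subclasses.items()},
                    "nodata": int(self.nodata),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "ClassScheme":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            classes=d["classes"],
            subclasses=d.get("subclasses", {}),
            nodata=d.get("nodata", -9999),
        )


#: Cultivated / ecological / construction / other with 100 m cells.
DEFAULT_SCHEME = ClassScheme()


@dataclass
class LandUseGrid:
    """Categorical raster of class codes; the CA state lattice.

    ``values`` is a 2-D integer array; ``cell_size`` is the square cell edge
    in meters (100 m by default); ``origin`` is the (x, y) of the lower-left
    corner. Two grids are aligned iff shape, cell size and origin all match.
    """

    values: np.ndarray
    cell_size: float = 100.0
    origin: tuple = (0.0, 0.0)
    epoch: str | None = None
    nodata: int = -9999

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("grid values must be integer class codes")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def aligned_with(self, other: "LandUseGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def class_counts(self, scheme: ClassScheme) -> dict:
        """Cell count per class name (nodata excluded)."""
        return {
            name: int(np.count_nonzero(self.values == code))
            for name, code in scheme.classes.items()
        }

    def copy(self, epoch: str | None = None) -> "LandUseGrid":
        return replace(self, values=self.values.copy(), epoch=epoch or self.epoch)

    def validate(self, scheme: ClassScheme) -> None:
        codes = set(scheme.codes) | {self.nodata}
        present = set(np.unique(self.values).tolist())
        unknown = present - codes
        if unknown:
            raise ValueError(f"unknown class code(s) {sorted(unknown)}")


@dataclass
class DriverStack:
    """Named continuous covariate rasters aligned to a land-use grid.

    Each layer is a float lattice in [0, 1] (NaN where nodata). Layers are
    stored in a dict keyed by the names in :data:`DRIVER_NAMES` (extra layers
    are allowed).
    """

    layers: dict
    cell_size: float = 100.0
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        shapes = {np.asarray(v).shape for v in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError("driver layers are not aligned (mixed shapes)")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}

    @property
    def names(self) -> tuple:
        return tuple(self.layers.keys())

    @property
    def shape(self) -> tuple:
        return next(iter(self.layers.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def design_matrix(self, names=None) -> np.ndarray:
        """(n_cells, n_layers) matrix of driver values, row-major cell order."""
        names = list(names) if names is not None else list(self.names)
        return np.column_stack([self.layers[n].ravel() for n in names])

    def validate(self) -> None:
        for name, layer in self.layers.items():
            finite = layer[np.isfinite(layer)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"driver {name!r} outside [0, 1] after normalization")


# ---------------------------------------------------------------------------
# ESRI ASCII Grid I/O


def _read_ascii_header(fh):
    header = {}
    pos = fh.tell()
    for _ in range(6):
        line = fh.readline()
        parts = line.split()
        if len(parts) != 2 or not parts[0][0].isalpha():
            fh.seek(pos)
            break
        header[parts[0].lower()] = parts[1]
        pos = fh.tell()
    return header


def _parse_grid_file(path):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = _read_ascii_header(fh)
        data = np.loadtxt(fh, ndmin=2)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if "cellsize" in header:
        cell = float(header["cellsize"])
    else:  # dx/dy variant
        dx, dy = float(header["dx"]), float(header["dy"])
        if dx != dy:
            raise ValueError("non-square cells are not supported")
        cell = dx
    x0 = float(header.get("xllcorner", 0.0))
    y0 = float(header.get("yllcorner", 0.0))
    nodata = float(header.get("nodata_value", -9999))
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid body {data.shape} does not match header ({nrows}, {ncols})")
    return data, cell, (x0, y0), nodata


def read_landuse_raster(path, scheme: ClassScheme = DEFAULT_SCHEME) -> LandUseGrid:
    """Read a categorical ESRI ASCII Grid; unknown codes raise, never remap."""
    data, cell, origin, nodata = _parse_grid_file(path)
    values = data.astype(np.int64)
    if not np.array_equal(values, data):
        raise ValueError("land-use raster contains non-integer values")
    grid = LandUseGrid(values, cell_size=cell, origin=origin, nodata=int(nodata))
    grid.validate(scheme)
    return grid


def write_landuse_raster(grid: LandUseGrid, path) -> None:
    """Write an ESRI ASCII Grid with bit-exact integer codes."""
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        np.savetxt(fh, grid.values, fmt="%d")


def read_float_raster(path):
    """Read a continuous ASCII Grid layer; nodata becomes NaN.

    Returns ``(layer, cell_size, origin)``.
    """
    data, cell, origin, nodata = _parse_grid_file(path)
    layer = data.astype(float)
    layer[layer == nodata] = np.nan
    return layer, cell, origin


def write_float_raster(layer, path, cell_size=100.0, origin=(0.0, 0.0), nodata=-9999.0):
    arr = np.asarray(layer, dtype=float).copy()
    arr[~np.isfinite(arr)] = nodata
    nrows, ncols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\n")
        fh.write(f"yllcorner {origin[1]:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, arr, fmt="%.8g")


# ---------------------------------------------------------------------------
# Driver normalization and area accounting


def normalize_driver(layer) -> np.ndarray:
    """Min–max rescale a continuous layer onto [0, 1], propagating NaN.

    The minimum finite value maps to 0, the maximum to 1, affine in between.
    A constant layer has an undefined range and raises ``ValueError``.
    """
    arr = np.asarray(layer, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("layer needs at least 2 finite values")
    lo, hi = finite.min(), finite.max()
    if lo == hi:
        raise ValueError("constant layer: min–max range is undefined")
    return (arr - lo) / (hi - lo)


def area_table(grid: LandUseGrid, scheme: ClassScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Per-class area (km²) and proportion (%) for one epoch.

    Proportions are over non-nodata cells and sum to 100.
    """
    counts = grid.class_counts(scheme)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("grid has no valid cells")
    rows = {
        name: {
            "area_km2": n * grid.cell_area_km2,
            "proportion_pct": 100.0 * n / total,
        }
        for name, n in counts.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "class"
    return df
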