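"""Gridded raster container and spherical cell-area model.

All layers in this package live on a regular north-up longitude/latitude
grid (WGS84).  The canonical global grid is 5 arc-minutes, 2160 rows by
4320 columns spanning 180W..180E, 90S..90N; synthetic miniature worlds use
the same container with coarser cells so every code path is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Authalic Earth radius in metres (sphere with the WGS84 ellipsoid's area).
EARTH_RADIUS_M = 6_371_007.2

#: Sentinel written to GeoTIFF files for ocean / no-data cells.
GEOTIFF_NODATA = -3.39999999999999996e38
#: Sentinel written to NetCDF files (float32-roundable).
NETCDF_NODATA = -3.4e38


@dataclass(frozen=True)
class GridGeoreference:
    """North-up geographic georeference: origin corner plus square cells.

    ``west`` / ``north`` locate the outer corner of cell (0, 0);
    ``cellsize`` is in decimal degrees.
    """

    rows: int
    cols: int
    west: float = -180.0
    north: float = 90.0
    cellsize: float = 1.0 / 12.0

    @classmethod
    def global_5min(cls) -> "GridGeoreference":
        return cls(rows=2160, cols=4320, west=-180.0, north=90.0, cellsize=1.0 / 12.0)

    def lat_center(self, row) -> np.ndarray | float:
        return self.north - (np.asarray(row) + 0.5) * self.cellsize

    def lon_center(self, col) -> np.ndarray | float:
        return self.west + (np.asarray(col) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        return self.lat_center(np.arange(self.rows))

    def lon_centers(self) -> np.ndarray:
        return self.lon_center(np.arange(self.cols))


@dataclass
class Grid5Min:
    """A single raster layer: values plus a no-data mask on a shared grid.

    ``values`` is float64 internally; masked cells hold 0 in ``values`` and
    True in ``mask``.  Units depend on the variable: 1000 ha for area
    layers, 1000 tonnes for production, t/ha for yield.
    """

    values: np.ndarray
    mask: np.ndarray
    geo: GridGeoreference

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.geo.rows, self.geo.cols):
            raise ValueError(
                f"layer shape {self.values.shape} does not match georeference "
                f"({self.geo.rows}, {self.geo.cols})"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")

    @classmethod
    def zeros(cls, geo: GridGeoreference) -> "Grid5Min":
        return cls(np.zeros((geo.rows, geo.cols)), np.zeros((geo.rows, geo.cols), bool), geo)

    @classmethod
    def full_like(cls, other: "Grid5Min", fill: float = 0.0) -> "Grid5Min":
        return cls(np.full(other.values.shape, fill, float), other.mask.copy(), other.geo)

    def copy(self) -> "Grid5Min":
        return Grid5Min(self.values.copy(), self.mask.copy(), self.geo)

    def same_grid(self, other: "Grid5Min") -> bool:
        return self.geo == other.geo

    def masked_total(self) -> float:
        return float(self.values[~self.mask].sum())


def cell_area(row: int | np.ndarray, geo: GridGeoreference) -> np.ndarray | float:
    """Area of a grid cell in the given row, in 1000 ha.

    On the authalic sphere the area of a lon/lat rectangle is
    R^2 * dlambda * (sin(phi_N) - sin(phi_S)); it depends only on the row.
    1000 ha = 1e7 m^2.
    """
    row = np.asarray(row)
    lat_n = np.deg2rad(geo.north - row * geo.cellsize)
    lat_s = np.deg2rad(geo.north - (row + 1) * geo.cellsize)
    dlam = np.deg2rad(geo.cellsize)
    area_m2 = EARTH_RADIUS_M**2 * dlam * (np.sin(lat_n) - np.sin(lat_s))
    out = area_m2 / 1e7
    return float(out) if out.ndim == 0 else out


@dataclass
class CellAreaModel:
    """Per-row cell areas (1000 ha) for one georeference, precomputed."""

    geo: GridGeoreference
    radius_m: float = EARTH_RADIUS_M
    row_areas: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.row_areas = np.asarray(cell_area(np.arange(self.geo.rows), self.geo))

    def area_of(self, row: int) -> float:
        return float(self.row_areas[row])

    def as_grid(self) -> np.ndarray:
        """(rows, cols) array of cell areas in 1000 ha."""
        return np.repeat(self.row_areas[:, None], self.geo.cols, axis=1)
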