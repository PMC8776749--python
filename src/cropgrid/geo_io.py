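"""Raster I/O with the published file conventions.

Annual layers are GeoTIFFs named
``GAEZAct2015_{Variable}_{Cropname}_{Management}.tif`` with Variable in
{HarvArea, Production, Yield} and Management in {Irrigated, Rainfed,
Total, Mean}; monthly cubes are NetCDF-4 files named
``GAEZ_CropArea_{Cropname}_{subcrop}_{Management}.nc`` with 12 layers and
internal compression.  Everything is WGS84 lon/lat, north-up, written as
float32 with the dataset's no-data sentinels (-3.39999999999999996e+38 for
GeoTIFF, -3.4e+38 for NetCDF).  Values are stored double precision in
memory and narrowed only on write.

The GeoTIFF layer is written directly through :mod:`tifffile` with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory pointing at EPSG:4326, GDAL_NODATA), uncompressed striped
layout.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import netCDF4
import numpy as np
import tifffile

from .grids import GEOTIFF_NODATA, NETCDF_NODATA, Grid5Min, GridGeoreference

__all__ = [
    "compose_filename",
    "write_raster",
    "read_raster",
    "write_monthly_netcdf",
    "read_monthly_netcdf",
    "ANNUAL_VARIABLES",
    "ANNUAL_MANAGEMENTS",
]

logger = logging.getLogger(__name__)

ANNUAL_VARIABLES = ("HarvArea", "Production", "Yield")
ANNUAL_MANAGEMENTS = ("Irrigated", "Rainfed", "Total", "Mean")
MONTHLY_MANAGEMENTS = ("Irrigated", "Rainfed")

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# Minimal GeoKey directory: geographic model, pixel-is-area, EPSG:4326
_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def compose_filename(
    variable: str,
    cropname: str,
    management: str,
    subcrop: int | None = None,
    year_tag: str = "2015",
) -> str:
    """File name following the published templates.

    Annual (``subcrop`` is None):
    ``GAEZAct{year}_{Variable}_{Cropname}_{Management}.tif``; monthly
    (``variable`` must be ``"CropArea"``):
    ``GAEZ_CropArea_{Cropname}_{subcrop}_{Management}.nc``.
    """
    if subcrop is None:
        if variable not in ANNUAL_VARIABLES:
            raise ValueError(f"invalid annual variable: {variable!r}")
        if management not in ANNUAL_MANAGEMENTS:
            raise ValueError(f"invalid management: {management!r}")
        return f"GAEZAct{year_tag}_{variable}_{cropname}_{management}.tif"
    if variable != "CropArea":
        raise ValueError("monthly files use variable 'CropArea'")
    if management not in MONTHLY_MANAGEMENTS:
        raise ValueError(f"invalid monthly management: {management!r}")
    if not 1 <= int(subcrop) <= 5:
        raise ValueError(f"subcrop must be 1..5, got {subcrop}")
    return f"GAEZ_CropArea_{cropname}_{int(subcrop)}_{management}.nc"


def write_raster(layer: Grid5Min, path) -> None:
    """Write one layer as an uncompressed striped float32 GeoTIFF."""
    geo = layer.geo
    data = np.where(layer.mask, GEOTIFF_NODATA, layer.values).astype(np.float32)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (geo.cellsize, geo.cellsize, 0.0), False),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geo.west, geo.north, 0.0), False),
        (_GEO_KEY_DIRECTORY, "H", len(_GEOKEYS), _GEOKEYS, False),
        (_GDAL_NODATA, "s", 0, repr(GEOTIFF_NODATA), False),
    ]
    tifffile.imwrite(path, data, extratags=extratags, compression=None)


def read_raster(path) -> Grid5Min:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        tags = page.tags
        if _MODEL_PIXEL_SCALE in tags and _MODEL_TIEPOINT in tags:
            scale = tags[_MODEL_PIXEL_SCALE].value
            tie = tags[_MODEL_TIEPOINT].value
            cellsize = float(scale[0])
            if abs(float(scale[1]) - cellsize) > 1e-12:
                raise ValueError("non-square cells are not supported")
            west, north = float(tie[3]), float(tie[4])
        else:
            warnings.warn(f"{path}: no georeferencing tags; assuming global grid")
            cellsize = 360.0 / values.shape[1]
            west, north = -180.0, 90.0
        if _GEO_KEY_DIRECTORY in tags:
            gk = tuple(tags[_GEO_KEY_DIRECTORY].value)
            keys = {gk[i]: gk[i + 3] for i in range(4, len(gk), 4)}
            if keys.get(2048, 4326) != 4326:
                warnings.warn(f"{path}: CRS is not EPSG:4326; coordinates assumed lon/lat")
        nodata = GEOTIFF_NODATA
        if _GDAL_NODATA in tags:
            nodata = float(tags[_GDAL_NODATA].value)
    rows, cols = values.shape
    geo = GridGeoreference(rows=rows, cols=cols, west=west, north=north, cellsize=cellsize)
    mask = values <= nodata * (1 - 1e-6) if nodata < 0 else values == nodata
    values = np.where(mask, 0.0, values)
    return Grid5Min(values, mask, geo)


def write_monthly_netcdf(
    data: np.ndarray,
    geo: GridGeoreference,
    path,
    mask: np.ndarray | None = None,
    var_name: str = "cropland_area",
    complevel: int = 7,
) -> None:
    """Write a 12-month stack as a compressed NetCDF-4 file.

    ``data`` must have shape (12, rows, cols) in 1000 ha.  An optional
    (rows, cols) mask marks no-data cells (stored as the -3.4e+38
    sentinel, also the variable's _FillValue).
    """
    data = np.asarray(data, dtype=np.float64)
    if data.shape != (12, geo.rows, geo.cols):
        raise ValueError(
            f"expected 12 monthly layers of shape ({geo.rows}, {geo.cols}), "
            f"got {data.shape}"
        )
    out = data.astype(np.float32)
    if mask is not None:
        out = np.where(np.asarray(mask, bool)[None, :, :], np.float32(NETCDF_NODATA), out)
    with netCDF4.Dataset(path, "w", format="NETCDF4") as ds:
        ds.createDimension("month", 12)
        ds.createDimension("lat", geo.rows)
        ds.createDimension("lon", geo.cols)
        vm = ds.createVariable("month", "i4", ("month",))
        vm[:] = np.arange(1, 13)
        vlat = ds.createVariable("lat", "f8", ("lat",))
        vlat[:] = geo.lat_centers()
        vlat.units = "degrees_north"
        vlon = ds.createVariable("lon", "f8", ("lon",))
        vlon[:] = geo.lon_centers()
        vlon.units = "degrees_east"
        v = ds.createVariable(
            var_name,
            "f4",
            ("month", "lat", "lon"),
            zlib=True,
            complevel=complevel,
            fill_value=np.float32(NETCDF_NODATA),
        )
        v[:] = out
        v.units = "1000 ha"
        ds.crs = "+proj=longlat +datum=WGS84"


def read_monthly_netcdf(path, var_name: str = "cropland_area"):
    """Read back a monthly NetCDF file -> (data (12, R, C), mask, geo)."""
    with netCDF4.Dataset(path, "r") as ds:
        v = ds.variables[var_name]
        v.set_auto_mask(True)
        arr = v[:]
        lat = np.asarray(ds.variables["lat"][:])
        lon = np.asarray(ds.variables["lon"][:])
    cellsize = float(abs(lat[0] - lat[1])) if len(lat) > 1 else float(lon[1] - lon[0])
    geo = GridGeoreference(
        rows=len(lat),
        cols=len(lon),
        west=float(lon[0] - cellsize / 2),
        north=float(lat[0] + cellsize / 2),
        cellsize=cellsize,
    )
    if np.ma.isMaskedArray(arr):
        mask2d = np.asarray(arr.mask).any(axis=0) if arr.mask is not np.ma.nomask else np.zeros((geo.rows, geo.cols), bool)
        data = np.asarray(arr.filled(0.0), dtype=np.float64)
    else:
        data = np.asarray(arr, dtype=np.float64)
        mask2d = np.zeros((geo.rows, geo.cols), bool)
    return data, mask2d, geo


def write_annual_result(result, out_dir, crops=None, managements=("Irrigated", "Rainfed")) -> list[str]:
    """Write an :class:`~cropgrid.grid_update.AnnualResult` as GeoTIFFs.

    Emits HarvArea, Production and Yield for each crop and requested
    management; the default (the two base managements) gives the
    3 x crops x 2 file inventory of the annual product.  Returns the file
    names written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    available_crops = sorted({c for _, c, _ in result.layers})
    for crop in crops or available_crops:
        for variable in ANNUAL_VARIABLES:
            for mgmt in managements:
                if mgmt in ("Total", "Mean"):
                    wanted = "Mean" if variable == "Yield" else "Total"
                    if mgmt != wanted:
                        continue
                    layer = result.total_layer(variable, crop)
                else:
                    layer = result.layers[(variable, crop, mgmt)]
                name = compose_filename(variable, crop, mgmt)
                write_raster(layer, out_dir / name)
                written.append(name)
    return written


def write_monthly_result(result, out_dir) -> list[str]:
    """Write a :class:`~cropgrid.monthly_disagg.MonthlyResult` as NetCDFs.

    One file per (crop, subcrop, management) with any nonzero area.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for (crop, mgmt), cube in sorted(result.cubes.items()):
        for n in range(cube.data.shape[0]):
            sub = cube.data[n]
            if not np.any(sub):
                continue
            name = compose_filename("CropArea", crop, mgmt, subcrop=n + 1)
            write_monthly_netcdf(sub, cube.geo, out_dir / name)
            written.append(name)
    return written
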