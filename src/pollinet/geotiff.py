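"""Minimal single-band WGS84 GeoTIFF reader/writer built on tifffile.

Only the subset of GeoTIFF needed here is supported: one band, north-up
geographic (EPSG:4326) grids with square pixels, georeferencing through
ModelPixelScale + ModelTiepoint, and NoData through the GDAL_NODATA ASCII
tag. Anything else (multi-band imagery, projected CRSs, rotated grids) is
rejected with an explicit error rather than guessed at.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import tifffile

from .grid import WGS84, GridSpec

# GeoTIFF / GDAL private tag codes
MODEL_PIXEL_SCALE = 33550
MODEL_TIEPOINT = 33922
GEO_KEY_DIRECTORY = 34735
GDAL_NODATA = 42113

# GeoKey ids
GT_MODEL_TYPE = 1024
GT_RASTER_TYPE = 1025
GEOGRAPHIC_TYPE = 2048

MODEL_TYPE_GEOGRAPHIC = 2
RASTER_PIXEL_IS_AREA = 1
GCS_WGS84 = 4326

_SQUARE_TOL = 1e-9


def _parse_geokeys(directory: tuple[int, ...]) -> dict[int, int]:
    """Flatten a GeoKeyDirectory short array into {key_id: value}.

    Only keys stored inline (TIFFTagLocation == 0) are returned; that covers
    the model-type and geographic-CS keys this reader needs.
    """
    keys: dict[int, int] = {}
    if len(directory) < 4:
        return keys
    n_keys = directory[3]
    for k in range(n_keys):
        base = 4 + 4 * k
        if base + 3 >= len(directory):
            break
        key_id, location, _count, value = directory[base : base + 4]
        if location == 0:
            keys[int(key_id)] = int(value)
    return keys


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band WGS84 GeoTIFF.

    Returns a float64 array with NoData cells as NaN, and the GridSpec
    recovered from the geo tags.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(
                f"{path.name}: expected a single-band raster, got array of shape {data.shape}"
            )
        samples = page.tags.get("SamplesPerPixel")
        if samples is not None and int(samples.value) != 1:
            raise ValueError(f"{path.name}: multi-band raster ({samples.value} samples per pixel)")

        geodir = page.tags.get(GEO_KEY_DIRECTORY)
        if geodir is None:
            raise ValueError(f"{path.name}: no GeoTIFF CRS tags found; WGS84 georeferencing required")
        keys = _parse_geokeys(tuple(int(v) for v in np.atleast_1d(geodir.value)))
        model_type = keys.get(GT_MODEL_TYPE)
        geog_type = keys.get(GEOGRAPHIC_TYPE)
        if model_type != MODEL_TYPE_GEOGRAPHIC or geog_type != GCS_WGS84:
            raise ValueError(
                f"{path.name}: CRS is not geographic WGS84 "
                f"(GTModelType={model_type}, GeographicType={geog_type}); "
                f"reproject to EPSG:4326 first"
            )

        scale_tag = page.tags.get(MODEL_PIXEL_SCALE)
        tiepoint_tag = page.tags.get(MODEL_TIEPOINT)
        if scale_tag is None or tiepoint_tag is None:
            raise ValueError(f"{path.name}: missing ModelPixelScale/ModelTiepoint georeferencing")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if not math.isclose(sx, sy, rel_tol=0.0, abs_tol=_SQUARE_TOL):
            raise ValueError(f"{path.name}: non-square pixels ({sx} x {sy} degrees) are unsupported")
        tp = tiepoint_tag.value
        # tiepoint maps raster (i, j, k) -> model (x=lon, y=lat, z)
        if float(tp[0]) != 0.0 or float(tp[1]) != 0.0:
            raise ValueError(f"{path.name}: only (0,0)-anchored tiepoints are supported")
        origin_lon, origin_lat = float(tp[3]), float(tp[4])

        nodata_tag = page.tags.get(GDAL_NODATA)

    values = data.astype(np.float64)
    if nodata_tag is not None:
        nodata = float(str(nodata_tag.value).strip())
        if math.isnan(nodata):
            pass  # NaN cells are already the missing marker
        else:
            values[data == np.asarray(nodata).astype(data.dtype)] = np.nan

    grid = GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        origin_lat=origin_lat,
        origin_lon=origin_lon,
        cell_size=sx,
        crs_id=WGS84,
    )
    return values, grid


def write_geotiff(
    path: str | Path,
    values: np.ndarray,
    grid: GridSpec,
    *,
    dtype: str = "float32",
    nodata: float | int | None = None,
) -> Path:
    """Write a single-band WGS84 GeoTIFF.

    NaN cells in ``values`` are written as ``nodata`` (which defaults to NaN
    for float output and must be given explicitly for integer output).
    """
    path = Path(path)
    values = np.asarray(values, dtype=np.float64)
    if values.shape != grid.shape:
        raise ValueError(f"array shape {values.shape} does not match grid {grid.shape}")

    out_dtype = np.dtype(dtype)
    has_nan = bool(np.isnan(values).any())
    if out_dtype.kind == "f":
        if nodata is None:
            nodata = float("nan")
        band = values.astype(out_dtype)
        if not math.isnan(float(nodata)):
            band = np.where(np.isnan(values), out_dtype.type(nodata), band)
    else:
        if has_nan and nodata is None:
            raise ValueError("integer output with missing cells requires an explicit nodata value")
        band = values.copy()
        if nodata is not None:
            band = np.where(np.isnan(band), float(nodata), band)
        band = band.astype(out_dtype)

    geokeys = (
        1, 1, 0, 3,
        GT_MODEL_TYPE, 0, 1, MODEL_TYPE_GEOGRAPHIC,
        GT_RASTER_TYPE, 0, 1, RASTER_PIXEL_IS_AREA,
        GEOGRAPHIC_TYPE, 0, 1, GCS_WGS84,
    )
    extratags = [
        (MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0), True),
        (GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys, True),
    ]
    if nodata is not None:
        nodata_str = "nan" if (isinstance(nodata, float) and math.isnan(nodata)) else repr(nodata)
        extratags.append((GDAL_NODATA, "s", 0, nodata_str, True))

    tifffile.imwrite(path, band, extratags=extratags)
    return path
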