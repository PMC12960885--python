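"""Plain-text I/O: ESRI ASCII grids for rasters, GeoJSON for vector layers.

The ASCII grid (.asc) format stores rows top-down (first data row = northern
edge); :class:`~bcmap.grid.GridRaster` uses row 0 = southern edge, so readers
and writers flip the row axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .grid import GridRaster

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_geojson",
    "read_geojson",
]

_NODATA = -9999


def write_ascii_grid(raster: GridRaster, path: str | Path) -> Path:
    path = Path(path)
    data = np.asarray(raster.data)
    if data.dtype == np.bool_:
        data = data.astype(np.int8)
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.x0}\n"
        f"yllcorner {raster.y0}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {_NODATA}\n"
    )
    fmt = "%d" if np.issubdtype(data.dtype, np.integer) else "%.4f"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data[::-1], fmt=fmt)
    return path


def read_ascii_grid(path: str | Path, dtype=None) -> GridRaster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, dtype=dtype if dtype is not None else float)
    data = np.atleast_2d(data)[::-1]
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {data.shape} does not match header in {path}")
    return GridRaster(
        data=data,
        cell_size=header["cellsize"],
        x0=header["xllcorner"],
        y0=header["yllcorner"],
    )


def write_geojson(geometries, path: str | Path, properties: list[dict] | None = None) -> Path:
    """Write shapely geometries (+ per-feature properties) as a GeoJSON FeatureCollection."""
    path = Path(path)
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties, strict=True)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def read_geojson(path: str | Path) -> tuple[list[shapely.Geometry], list[dict]]:
    with open(path) as fh:
        collection = json.load(fh)
    geoms = [shape(feat["geometry"]) for feat in collection["features"]]
    props = [feat.get("properties", {}) for feat in collection["features"]]
    return geoms, props
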