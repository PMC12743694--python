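"""Minimal raster containers for single-band grids in a projected metric CRS.

All analysis rasters (land cover, elevation, resistance, current) share one
grid geometry: an axis-aligned regular grid with square cells, row 0 at the
northern edge. Rasters are serialised as ESRI ASCII grids (plain text), and
vectors as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


class CRSMismatchError(ValueError):
    """Inputs are not in one shared projected CRS; reprojection is out of scope."""


class GeometryMismatchError(ValueError):
    """Two rasters that must share a grid geometry do not."""


@dataclass(frozen=True)
class GridGeometry:
    """Affine geometry of a north-up regular grid.

    ``x0`` is the western edge, ``y1`` the northern edge, both in metres of the
    projected CRS. Cell centres: ``x = x0 + (col + 0.5) * cell``,
    ``y = y1 - (row + 0.5) * cell``.
    """

    x0: float
    y1: float
    cell: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.x0,
            self.y1 - self.nrows * self.cell,
            self.x0 + self.ncols * self.cell,
            self.y1,
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell centre coordinates as two (nrows, ncols) arrays (x, y)."""
        cols = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        rows = self.y1 - (np.arange(self.nrows) + 0.5) * self.cell
        x, y = np.meshgrid(cols, rows)
        return x, y

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell


@dataclass
class Raster:
    """A single-band raster: values + geometry + CRS identifier."""

    values: np.ndarray
    geom: GridGeometry
    crs: str = "EPSG:32645"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.geom.nrows, self.geom.ncols):
            raise GeometryMismatchError(
                f"value shape {self.values.shape} does not match geometry "
                f"({self.geom.nrows}, {self.geom.ncols})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """True where the cell is inside the analysis extent."""
        vals = self.values
        if np.issubdtype(vals.dtype, np.floating):
            return ~np.isnan(vals) & (vals != self.nodata)
        return vals != self.nodata

    def copy_with(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values))


def check_same_geometry(a: Raster, b: Raster) -> None:
    if a.geom != b.geom:
        raise GeometryMismatchError(f"grid geometries differ: {a.geom} vs {b.geom}")
    if a.crs != b.crs:
        raise CRSMismatchError(f"CRS differ: {a.crs!r} vs {b.crs!r}")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text single-band raster)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    geom = raster.geom
    xll, yll = geom.x0, geom.y1 - geom.nrows * geom.cell
    vals = raster.values
    if np.issubdtype(vals.dtype, np.floating):
        body = np.where(np.isnan(vals), raster.nodata, vals)
        fmt = "%.8g"
    else:
        body = vals
        fmt = "%d"
    header = (
        f"ncols {geom.ncols}\n"
        f"nrows {geom.nrows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {geom.cell!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt=fmt)


def read_ascii_grid(path: str | Path, crs: str = "EPSG:32645", dtype=None) -> Raster:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=dtype if dtype is not None else float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    geom = GridGeometry(
        x0=header["xllcorner"],
        y1=header["yllcorner"] + nrows * header["cellsize"],
        cell=header["cellsize"],
        nrows=nrows,
        ncols=ncols,
    )
    return Raster(values=values, geom=geom, crs=crs, nodata=header["nodata_value"])


# ---------------------------------------------------------------------------
# GeoJSON I/O for shapely geometries


def write_geojson(geoms, path: str | Path, properties=None, crs: str = "EPSG:32645") -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    if isinstance(geoms, BaseGeometry):
        geoms = [geoms]
    geoms = list(geoms)
    if properties is None:
        properties = [{} for _ in geoms]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, properties, strict=True)
    ]
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_geojson(path: str | Path) -> list[BaseGeometry]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in doc["features"]]
    if doc.get("type") == "Feature":
        return [shape(doc["geometry"])]
    return [shape(doc)]
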