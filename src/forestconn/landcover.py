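"""Land-cover preparation: reclassification, resampling, elevation masking,
footprint burning, and two-date deforestation detection.

Land cover uses five broad classes tuned to forest-habitat connectivity:
forest (incl. other wooded land), grassland, cropland, waterbodies (incl.
riverbed), and unsuitable (glaciers, snow, built-up, bare soil/rock, and any
project-converted area). Above the regional tree line (3600 m a.s.l. by
default) every cell is unsuitable regardless of cover.
"""

from __future__ import annotations

import math
from enum import IntEnum

import numpy as np
from shapely.geometry.base import BaseGeometry

from .grids import GeometryMismatchError, Raster, check_same_geometry


class LandCoverClass(IntEnum):
    FOREST = 1
    GRASSLAND = 2
    CROPLAND = 3
    WATERBODIES = 4
    UNSUITABLE = 5


class ChangeClass(IntEnum):
    OTHER = 0
    STABLE_FOREST = 1
    DEFORESTED = 2


LANDCOVER_NODATA = 0

#: Default raw-class → broad-class mapping (national land-cover nomenclature).
DEFAULT_RECLASS_MAP: dict[str, LandCoverClass] = {
    "forest": LandCoverClass.FOREST,
    "other wooded land": LandCoverClass.FOREST,
    "grassland": LandCoverClass.GRASSLAND,
    "cropland": LandCoverClass.CROPLAND,
    "water body": LandCoverClass.WATERBODIES,
    "riverbed": LandCoverClass.WATERBODIES,
    "glacier": LandCoverClass.UNSUITABLE,
    "snow": LandCoverClass.UNSUITABLE,
    "built-up area": LandCoverClass.UNSUITABLE,
    "bare soil": LandCoverClass.UNSUITABLE,
    "bare rock": LandCoverClass.UNSUITABLE,
}


class UnmappedClassError(KeyError):
    """A raw class code present in the raster has no reclassification entry."""


def reclassify(raw: Raster, mapping: dict) -> Raster:
    """Collapse raw land-cover codes into the five broad classes.

    ``mapping`` maps each raw code (int or str label pre-encoded as int keys)
    to a :class:`LandCoverClass`. Every raw code present in the raster must
    have an entry; NoData passes through.
    """
    vals = raw.values
    out = np.full(vals.shape, LANDCOVER_NODATA, dtype=np.uint8)
    valid = raw.valid_mask()
    present = np.unique(vals[valid])
    missing = [c for c in present if c not in mapping]
    if missing:
        raise UnmappedClassError(f"no reclassification entry for raw class(es) {missing}")
    for code in present:
        out[valid & (vals == code)] = int(mapping[code])
    return Raster(out, raw.geom, crs=raw.crs, nodata=LANDCOVER_NODATA)


def resample_nearest(lc: Raster, target_cell_size: float) -> Raster:
    """Nearest-neighbour resampling to a coarser square grid.

    Each output cell takes the class of the source cell whose centre is
    nearest the output cell centre; equidistant ties break toward the source
    cell with the smaller row, then smaller column index.
    """
    if target_cell_size <= 0:
        raise ValueError(f"target cell size must be positive, got {target_cell_size}")
    src = lc.geom
    if target_cell_size < src.cell:
        raise ValueError("target cell size must be >= source cell size")
    if target_cell_size == src.cell:
        return lc.copy_with(lc.values.copy())
    width = src.ncols * src.cell
    height = src.nrows * src.cell
    ncols = max(1, math.ceil(width / target_cell_size))
    nrows = max(1, math.ceil(height / target_cell_size))
    from .grids import GridGeometry

    out_geom = GridGeometry(src.x0, src.y1, target_cell_size, nrows, ncols)
    xc = src.x0 + (np.arange(ncols) + 0.5) * target_cell_size
    yc = src.y1 - (np.arange(nrows) + 0.5) * target_cell_size
    # fractional source index of each output centre; ceil(f - 0.5) rounds to
    # nearest and resolves exact half-way ties toward the smaller index
    fcol = (xc - src.x0) / src.cell - 0.5
    frow = (src.y1 - yc) / src.cell - 0.5
    col_idx = np.ceil(fcol - 0.5).astype(int).clip(0, src.ncols - 1)
    row_idx = np.ceil(frow - 0.5).astype(int).clip(0, src.nrows - 1)
    values = lc.values[np.ix_(row_idx, col_idx)]
    return Raster(values, out_geom, crs=lc.crs, nodata=lc.nodata)


def apply_elevation_mask(lc: Raster, dem: Raster, threshold: float = 3600.0) -> Raster:
    """Mark every cell strictly above ``threshold`` metres as unsuitable.

    Cells at exactly the threshold elevation keep their class.
    """
    check_same_geometry(lc, dem)
    out = lc.values.copy()
    above = dem.valid_mask() & (dem.values > threshold) & lc.valid_mask()
    out[above] = LandCoverClass.UNSUITABLE
    return lc.copy_with(out)


def burn_footprint(lc: Raster, footprint: BaseGeometry) -> Raster:
    """Convert cells whose centre lies inside the project footprint to unsuitable.

    Produces the after-construction scenario land cover. Idempotent.
    """
    import shapely

    if footprint is None or footprint.is_empty or not footprint.is_valid:
        raise ValueError("footprint polygon is empty or invalid")
    x, y = lc.geom.cell_centres()
    inside = shapely.contains_xy(footprint, x.ravel(), y.ravel()).reshape(lc.shape)
    out = lc.values.copy()
    out[inside & lc.valid_mask()] = LandCoverClass.UNSUITABLE
    return lc.copy_with(out)


#: Classes counting as "converted" in the deforestation definition.
_DEFOREST_TARGETS = (LandCoverClass.CROPLAND, LandCoverClass.UNSUITABLE)


def detect_deforestation(lc_t1: Raster, lc_t2: Raster) -> Raster:
    """Per-cell change classes between two dates.

    ``deforested``: forest at date 1 converted to cropland or unsuitable by
    date 2. ``stable_forest``: forest at both dates. Everything else
    (including forest→grassland and forest→waterbodies) is ``other``.
    """
    check_same_geometry(lc_t1, lc_t2)
    v1, v2 = lc_t1.values, lc_t2.values
    out = np.full(v1.shape, ChangeClass.OTHER, dtype=np.uint8)
    forest1 = v1 == LandCoverClass.FOREST
    out[forest1 & (v2 == LandCoverClass.FOREST)] = ChangeClass.STABLE_FOREST
    out[forest1 & np.isin(v2, _DEFOREST_TARGETS)] = ChangeClass.DEFORESTED
    valid = lc_t1.valid_mask() & lc_t2.valid_mask()
    out[~valid] = ChangeClass.OTHER
    return Raster(out, lc_t1.geom, crs=lc_t1.crs, nodata=255)
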