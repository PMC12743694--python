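"""Seeded synthetic landscapes for driving and testing the connectivity pipeline.

Real inputs to the analysis are a two-date national land-cover product, a DEM,
a project footprint and a river network, none of which ship with the package.
This module generates structurally equivalent synthetic inputs: a five-class
land cover with tunable forest fragmentation, a meandering river rasterised to
waterbodies, an elevation gradient crossing the tree line, a reservoir-like
project footprint straddling the river, and a second-date land cover in which
clustered forest patches have been converted to cropland or unsuitable.

All randomness is driven by a single integer seed; identical configurations
produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box

from .grids import GridGeometry, Raster
from .landcover import LandCoverClass

_CRS = "EPSG:32645"


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Defaults emulate the study setting: 60 m cells, a predominantly forested
    (~60%) landscape, a river corridor, a footprint on the river, an elevation
    gradient from valley floor past the 3600 m tree line, and modest
    deforestation between the two dates.
    """

    width: int = 160
    height: int = 160
    cell_size: float = 60.0
    forest_fraction: float = 0.6
    fragmentation: float = 8.0
    river_width: int = 2
    footprint_fraction: float = 0.02
    deforestation_fraction: float = 0.04
    elevation_range: tuple[float, float] = (200.0, 4000.0)
    seed: int = 0
    cropland_share_of_loss: float = 0.7  # remainder of deforested cells → unsuitable

    def validate(self) -> None:
        fracs = {
            "forest_fraction": self.forest_fraction,
            "footprint_fraction": self.footprint_fraction,
            "deforestation_fraction": self.deforestation_fraction,
            "cropland_share_of_loss": self.cropland_share_of_loss,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.width < 8 or self.height < 8:
            raise ValueError("width and height must be >= 8 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.fragmentation <= 0:
            raise ValueError("fragmentation (smoothing length) must be positive")
        if self.elevation_range[0] >= self.elevation_range[1]:
            raise ValueError("elevation_range must be (min, max) with min < max")


@dataclass
class SyntheticLandscape:
    """Bundle of generated inputs."""

    landcover_2000: Raster
    landcover_2019: Raster
    elevation: Raster
    footprint: Polygon
    rivers: list[LineString]
    config: LandscapeConfig = field(repr=False, default=None)

    def __iter__(self):
        return iter(
            (self.landcover_2000, self.landcover_2019, self.elevation, self.footprint, self.rivers)
        )


def _smooth_noise(rng: np.ndarray, shape: tuple[int, int], length: float) -> np.ndarray:
    """Gaussian-smoothed white noise, standardised to zero mean / unit sd."""
    from scipy.ndimage import gaussian_filter

    noise = rng.standard_normal(shape)
    field = gaussian_filter(noise, sigma=length, mode="reflect")
    return (field - field.mean()) / field.std()


def _threshold_to_fraction(field: np.ndarray, eligible: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask selecting the top ``fraction`` of eligible cells by field value."""
    n_el = int(eligible.sum())
    k = int(round(fraction * n_el))
    if k <= 0:
        return np.zeros_like(eligible)
    if k >= n_el:
        return eligible.copy()
    vals = field[eligible]
    cut = np.partition(vals, n_el - k)[n_el - k]
    mask = eligible & (field >= cut)
    # exact count: drop surplus boundary cells deterministically (row-major order)
    surplus = int(mask.sum()) - k
    if surplus > 0:
        rows, cols = np.nonzero(mask & (field == cut))
        for r, c in zip(rows[:surplus], cols[:surplus]):
            mask[r, c] = False
    return mask


def _river_line(geom: GridGeometry, rng) -> LineString:
    """A meandering line traversing the extent south to north."""
    xmin, ymin, xmax, ymax = geom.bounds
    n_pts = 24
    ys = np.linspace(ymin - geom.cell, ymax + geom.cell, n_pts)
    xmid = 0.5 * (xmin + xmax)
    amp = 0.18 * (xmax - xmin)
    phase = rng.uniform(0, 2 * np.pi)
    xs = xmid + amp * np.sin(np.linspace(0, 3 * np.pi, n_pts) + phase)
    xs += rng.normal(0, 0.02 * (xmax - xmin), n_pts)
    return LineString(np.column_stack([xs, ys]))


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Generate the full synthetic input set for one seed.

    Returns two-date land cover, elevation, a project footprint polygon
    overlapping forest and river, and the river polylines.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    geom = GridGeometry(
        x0=400_000.0, y1=3_000_000.0, cell=config.cell_size, nrows=config.height, ncols=config.width
    )
    shape = (config.height, config.width)
    x, y = geom.cell_centres()

    # elevation: south->north linear gradient + smooth noise
    lo, hi = config.elevation_range
    grad = (y - y.min()) / (y.max() - y.min() + 1e-12)
    elev_noise = _smooth_noise(rng, shape, max(config.fragmentation, 2.0))
    elev = lo + grad * (hi - lo) + 0.04 * (hi - lo) * elev_noise
    elevation = Raster(elev.astype(np.float32), geom, crs=_CRS, nodata=-9999.0)

    # river rasterised to waterbodies
    river = _river_line(geom, rng)
    half_w = 0.5 * config.river_width * config.cell_size
    river_mask = shapely.dwithin(
        shapely.points(np.column_stack([x.ravel(), y.ravel()])), river, half_w
    ).reshape(shape)

    # forest from thresholded smoothed noise on non-river cells
    forest_field = _smooth_noise(rng, shape, config.fragmentation)
    eligible = ~river_mask
    forest_mask = _threshold_to_fraction(forest_field, eligible, config.forest_fraction)

    # remaining land split grassland/cropland/unsuitable by a second field
    lc2000 = np.full(shape, LandCoverClass.CROPLAND, dtype=np.uint8)
    other_field = _smooth_noise(rng, shape, max(config.fragmentation / 2.0, 1.0))
    rest = eligible & ~forest_mask
    lc2000[rest & (other_field > 0.7)] = LandCoverClass.GRASSLAND
    lc2000[rest & (other_field < -1.1)] = LandCoverClass.UNSUITABLE
    lc2000[forest_mask] = LandCoverClass.FOREST
    lc2000[river_mask] = LandCoverClass.WATERBODIES

    # footprint: reservoir-like rectangle centred on the river mid-extent
    xmin, ymin, xmax, ymax = geom.bounds
    area = config.footprint_fraction * (xmax - xmin) * (ymax - ymin)
    aspect = 2.5  # elongated along the river
    fh = float(np.sqrt(area * aspect))
    fw = float(area / fh) if fh > 0 else 0.0
    ymid = 0.5 * (ymin + ymax)
    xr = float(river.interpolate(river.project(shapely.Point(0.5 * (xmin + xmax), ymid))).x)
    footprint = box(xr - fw / 2, ymid - fh / 2, xr + fw / 2, ymid + fh / 2)

    # guarantee the footprint overlaps at least one forest cell
    fp_cells = shapely.contains_xy(footprint, x.ravel(), y.ravel()).reshape(shape)
    if fp_cells.any() and not (fp_cells & (lc2000 == LandCoverClass.FOREST)).any():
        cand = fp_cells & ~river_mask
        if cand.any():
            idx = np.unravel_index(np.argmax(np.where(cand, forest_field, -np.inf)), shape)
            lc2000[idx] = LandCoverClass.FOREST

    # deforestation 2000 -> 2019: clustered subset of forest converted
    defo_field = _smooth_noise(rng, shape, max(config.fragmentation / 2.0, 1.0))
    forest2000 = lc2000 == LandCoverClass.FOREST
    defo_mask = _threshold_to_fraction(defo_field, forest2000, config.deforestation_fraction)
    lc2019 = lc2000.copy()
    to_crop = rng.random(shape) < config.cropland_share_of_loss
    lc2019[defo_mask & to_crop] = LandCoverClass.CROPLAND
    lc2019[defo_mask & ~to_crop] = LandCoverClass.UNSUITABLE

    return SyntheticLandscape(
        landcover_2000=Raster(lc2000, geom, crs=_CRS, nodata=0),
        landcover_2019=Raster(lc2019, geom, crs=_CRS, nodata=0),
        elevation=elevation,
        footprint=footprint,
        rivers=[river],
        config=config,
    )


# ---------------------------------------------------------------------------
# Deterministic pinch-corridor fixture


@dataclass
class PinchFixture:
    """Two forest blocks joined by a single narrow corridor, and the same
    landscape after the corridor is destroyed by the project footprint."""

    before: Raster
    after: Raster
    footprint: Polygon
    corridor_mask: np.ndarray
    block_mask: np.ndarray


def pinch_fixture(
    size: int = 60, cell_size: float = 60.0, corridor_width: int = 3
) -> PinchFixture:
    """Build the pinch-corridor scenario pair.

    Two large forest blocks sit in otherwise unsuitable terrain, connected
    only by a ``corridor_width``-cell-wide forest corridor. The after scenario
    burns the corridor (the project footprint) to unsuitable; nothing else
    changes. All geometry is deterministic.
    """
    geom = GridGeometry(x0=400_000.0, y1=3_000_000.0, cell=cell_size, nrows=size, ncols=size)
    lc = np.full((size, size), LandCoverClass.UNSUITABLE, dtype=np.uint8)

    r0, r1 = size // 6, size - size // 6  # block rows
    lw = size * 2 // 5  # left block east edge (exclusive)
    rw = size - lw  # right block west edge
    block = np.zeros((size, size), dtype=bool)
    block[r0:r1, 2:lw] = True
    block[r0:r1, rw : size - 2] = True

    mid = size // 2
    c0 = mid - corridor_width // 2
    corridor = np.zeros((size, size), dtype=bool)
    corridor[c0 : c0 + corridor_width, lw:rw] = True

    lc[block] = LandCoverClass.FOREST
    lc[corridor] = LandCoverClass.FOREST

    before = Raster(lc, geom, crs=_CRS, nodata=0)

    # footprint covers exactly the corridor cells (cell-centre containment)
    x_w = geom.x0 + lw * cell_size
    x_e = geom.x0 + rw * cell_size
    y_n = geom.y1 - c0 * cell_size
    y_s = geom.y1 - (c0 + corridor_width) * cell_size
    footprint = box(x_w, y_s, x_e, y_n)

    after_vals = lc.copy()
    after_vals[corridor] = LandCoverClass.UNSUITABLE
    after = Raster(after_vals, geom, crs=_CRS, nodata=0)

    return PinchFixture(
        before=before,
        after=after,
        footprint=footprint,
        corridor_mask=corridor,
        block_mask=block,
    )
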