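import numpy as np
import pytest

from forestconn.grids import GridGeometry, Raster


@pytest.fixture
def small_geom():
    return GridGeometry(x0=0.0, y1=600.0, cell=60.0, nrows=10, ncols=10)


@pytest.fixture
def uniform_resistance(small_geom):
    return Raster(np.ones((10, 10)), small_geom, nodata=np.nan)


def make_raster(values, cell=60.0, nodata=np.nan, crs="EPSG:32645"):
    values = np.asarray(values, dtype=float if nodata is np.nan else None)
    nrows, ncols = values.shape
    geom = GridGeometry(x0=0.0, y1=nrows * cell, cell=cell, nrows=nrows, ncols=ncols)
    return Raster(values, geom, crs=crs, nodata=nodata)
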