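"""Ensemble consensus and before/after change mapping.

The factorial resistance ensemble yields one cumulative current map per
profile. Many members are near-duplicates (rank correlation ρ > 0.99); the
consensus map keeps one representative per duplicate cluster (greedy
keep-first scan in profile order) and sums the retained maps. The impact map
is the signed percent change of consensus current density from the
before-construction to the after-construction scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .grids import Raster, check_same_geometry

DEFAULT_RHO_THRESHOLD = 0.99


def spearman_dedup(
    maps: list[Raster], rho_threshold: float = DEFAULT_RHO_THRESHOLD
) -> list[Raster]:
    """Greedy rank-correlation deduplication of current maps.

    Scanning in profile order, a map is retained iff its Spearman ρ with every
    already-retained map is ≤ ``rho_threshold``. ρ is computed over valid
    (non-NoData) cells with average ranks for ties.
    """
    if not maps:
        raise ValueError("need at least one current map")
    for m in maps[1:]:
        check_same_geometry(maps[0], m)
    valid = maps[0].valid_mask()
    for m in maps[1:]:
        valid &= m.valid_mask()
    vectors = [m.values[valid].astype(float) for m in maps]
    retained: list[int] = []
    for idx, vec in enumerate(vectors):
        dup = False
        for kept in retained:
            rho = spearmanr(vec, vectors[kept]).statistic
            if np.isnan(rho):  # constant map: ranks undefined; treat as duplicate
                rho = 1.0
            if rho > rho_threshold:
                dup = True
                break
        if not dup:
            retained.append(idx)
    return [maps[i] for i in retained]


@dataclass
class ConsensusCurrentMap:
    """Element-wise sum of the retained ensemble maps for one scenario."""

    raster: Raster
    retained_profile_ids: list[int]
    rho_threshold: float = DEFAULT_RHO_THRESHOLD

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def sum_consensus(
    retained: list[Raster], rho_threshold: float = DEFAULT_RHO_THRESHOLD
) -> ConsensusCurrentMap:
    """Sum retained maps element-wise, recording which profiles contributed."""
    if not retained:
        raise ValueError("need at least one retained map")
    for m in retained[1:]:
        check_same_geometry(retained[0], m)
    total = np.zeros(retained[0].shape)
    valid = retained[0].valid_mask()
    for m in retained:
        valid &= m.valid_mask()
        total += np.nan_to_num(m.values, nan=0.0)
    total = np.where(valid, total, np.nan)
    raster = Raster(total, retained[0].geom, crs=retained[0].crs, nodata=np.nan)
    ids = [getattr(m, "profile_id", None) for m in retained]
    ids = [i for i in ids if i is not None]
    return ConsensusCurrentMap(raster=raster, retained_profile_ids=ids, rho_threshold=rho_threshold)


@dataclass
class ChangeMap:
    """Signed percent change of current density, with an undefined-cell mask."""

    values: np.ndarray  # percent; NaN where undefined
    mask: np.ndarray  # True where change is undefined
    raster: Raster = field(repr=False, default=None)


def percent_change(before: ConsensusCurrentMap, after: ConsensusCurrentMap) -> ChangeMap:
    """100 × (after − before) / before, per cell.

    Cells where both scenarios carry zero current are 0% change; cells where
    current appears from a zero baseline are masked undefined.
    """
    check_same_geometry(before.raster, after.raster)
    b = before.values
    a = after.values
    valid = before.raster.valid_mask() & after.raster.valid_mask()
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (a - b) / b
    both_zero = valid & (b == 0) & (a == 0)
    change[both_zero] = 0.0
    undefined = ~valid | ((b == 0) & (a > 0))
    change[undefined] = np.nan
    raster = Raster(change, before.raster.geom, crs=before.raster.crs, nodata=np.nan)
    return ChangeMap(values=change, mask=undefined, raster=raster)
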