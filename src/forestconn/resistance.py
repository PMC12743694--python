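"""Factorial resistance-surface ensemble.

Rather than parameterising a single species-specific resistance surface, the
analysis sweeps a factorial set of resistance profiles spanning plausible
landscape permeabilities: forest is always the most permeable class
(resistance 1), unsuitable always the least (100), and cropland, grassland
and waterbodies each take low (10), medium (50) or high (90) resistance in
every combination — 3 × 3 × 3 = 27 profiles by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Raster
from .landcover import LandCoverClass

FOREST_RESISTANCE = 1.0
UNSUITABLE_RESISTANCE = 100.0
DEFAULT_VARIABLE_LEVELS: dict[str, tuple[float, ...]] = {
    "cropland": (10.0, 50.0, 90.0),
    "grassland": (10.0, 50.0, 90.0),
    "waterbodies": (10.0, 50.0, 90.0),
}


@dataclass(frozen=True)
class ResistanceProfile:
    """One class→resistance assignment; forest and unsuitable are fixed."""

    profile_id: int
    cropland: float
    grassland: float
    waterbodies: float
    forest: float = FOREST_RESISTANCE
    unsuitable: float = UNSUITABLE_RESISTANCE

    def __post_init__(self) -> None:
        for name in ("forest", "grassland", "cropland", "waterbodies", "unsuitable"):
            r = getattr(self, name)
            if not 1.0 <= r <= 100.0:
                raise ValueError(f"resistance for {name} must be in [1, 100], got {r}")

    def as_lookup(self) -> dict[int, float]:
        return {
            int(LandCoverClass.FOREST): self.forest,
            int(LandCoverClass.GRASSLAND): self.grassland,
            int(LandCoverClass.CROPLAND): self.cropland,
            int(LandCoverClass.WATERBODIES): self.waterbodies,
            int(LandCoverClass.UNSUITABLE): self.unsuitable,
        }


def enumerate_profiles(
    levels: dict[str, tuple[float, ...]] | None = None,
) -> list[ResistanceProfile]:
    """Full Cartesian product of per-class resistance levels.

    Ordered lexicographically by (cropland, grassland, waterbodies) level;
    ``profile_id`` is the 0-based position in that order.
    """
    levels = dict(DEFAULT_VARIABLE_LEVELS if levels is None else levels)
    for cls in ("cropland", "grassland", "waterbodies"):
        if not levels.get(cls):
            raise ValueError(f"empty resistance level list for class {cls!r}")
    combos = product(levels["cropland"], levels["grassland"], levels["waterbodies"])
    return [
        ResistanceProfile(profile_id=i, cropland=c, grassland=g, waterbodies=w)
        for i, (c, g, w) in enumerate(combos)
    ]


def build_resistance_surface(lc: Raster, profile: ResistanceProfile) -> Raster:
    """Rasterise a profile over a five-class land cover; NoData propagates as NaN."""
    lookup = profile.as_lookup()
    table = np.full(256, np.nan)
    for code, r in lookup.items():
        table[code] = r
    vals = table[lc.values.astype(np.intp)]
    vals[~lc.valid_mask()] = np.nan
    out = Raster(vals.astype(np.float64), lc.geom, crs=lc.crs, nodata=np.nan)
    out.profile_id = profile.profile_id
    return out


def profiles_manifest(profiles: list[ResistanceProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "profile_id": p.profile_id,
                "forest": p.forest,
                "grassland": p.grassland,
                "cropland": p.cropland,
                "waterbodies": p.waterbodies,
                "unsuitable": p.unsuitable,
            }
            for p in profiles
        ]
    )


def write_manifest(profiles: list[ResistanceProfile], path: str | Path) -> None:
    profiles_manifest(profiles).to_csv(path, index=False)
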