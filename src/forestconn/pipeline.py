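"""End-to-end orchestration: impact assessment and offset prioritisation.

``run_impact`` builds the before/after-construction scenarios, runs the full
factorial resistance ensemble through the circuit solver with one shared
focal-node set, deduplicates and sums the per-profile current maps, and
returns the consensus maps plus the percent-change map.

``run_offset`` then detects deforestation between the two land-cover dates,
tessellates the extent into 10-ha hexagons, filters deforested candidates by
current-density percentile, scores each by varIIC at every dispersal
threshold, and ranks them landscape-wide and for the riparian subset.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import circuit, consensus, landcover, prioritise, resistance
from .grids import Raster, write_ascii_grid, write_geojson
from .synthetic import LandscapeConfig, SyntheticLandscape, generate_landscape

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    resistance_levels: dict | None = None
    n_focal_nodes: int = 50
    buffer_width: float | None = None  # metres; None -> fraction of extent
    buffer_fraction: float = 0.2
    rho_threshold: float = consensus.DEFAULT_RHO_THRESHOLD
    percentile_q: float = 20.0
    dispersal_distances: tuple[float, ...] = prioritise.DEFAULT_DISPERSAL_DISTANCES
    lost_forest_area: float | None = None  # m²; None -> measured from scenarios
    elevation_threshold: float = 3600.0
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        self.landscape.validate()
        if any(d <= 0 for d in self.dispersal_distances):
            raise ValueError("dispersal distances must be positive")
        if list(self.dispersal_distances) != sorted(self.dispersal_distances):
            raise ValueError("dispersal distances must be sorted ascending")
        if self.n_focal_nodes < 2:
            raise ValueError("need at least 2 focal nodes")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ImpactResult:
    before: consensus.ConsensusCurrentMap
    after: consensus.ConsensusCurrentMap
    change: consensus.ChangeMap
    focal: circuit.FocalNodeSet
    scenario_before: Raster
    scenario_after: Raster
    landscape: SyntheticLandscape
    study_area: object  # shapely polygon
    report: dict


@dataclass
class OffsetResult:
    ranking: prioritise.PriorityRanking
    riparian_ranking: prioritise.PriorityRanking | None
    candidates: list
    riparian_candidates: list
    patches: list
    change_classes: Raster
    report: dict


def _study_area(raster: Raster, buffer_width: float):
    """Inner study-area rectangle: the raster extent inset by the buffer width,
    leaving the outer ring available for focal-node placement."""
    xmin, ymin, xmax, ymax = raster.geom.bounds
    inner = box(xmin + buffer_width, ymin + buffer_width, xmax - buffer_width, ymax - buffer_width)
    if inner.is_empty or inner.area <= 0:
        raise ValueError("buffer width leaves no interior study area")
    return inner


def prepare_scenarios(
    land: SyntheticLandscape, elevation_threshold: float = 3600.0
) -> tuple[Raster, Raster]:
    """Before- and after-construction land covers from the raw inputs.

    Before = latest-date land cover with the above-tree-line mask applied;
    after = before with the project footprint burned to unsuitable.
    """
    before = landcover.apply_elevation_mask(
        land.landcover_2019, land.elevation, elevation_threshold
    )
    after = landcover.burn_footprint(before, land.footprint)
    return before, after


def ensemble_current_maps(
    lc: Raster,
    profiles: list[resistance.ResistanceProfile],
    focal: circuit.FocalNodeSet,
) -> list[Raster]:
    """One cumulative current map per resistance profile, same focal nodes."""
    maps = []
    for prof in profiles:
        surface = resistance.build_resistance_surface(lc, prof)
        graph = circuit.build_network(surface)
        maps.append(circuit.cumulative_current(graph, focal))
    return maps


def run_impact(config: RunConfig, land: SyntheticLandscape | None = None) -> ImpactResult:
    """Full before/after connectivity-impact assessment."""
    config.validate()
    if land is None:
        land = generate_landscape(config.landscape)
    scen_before, scen_after = prepare_scenarios(land, config.elevation_threshold)

    profiles = resistance.enumerate_profiles(config.resistance_levels)
    buffer_width = config.buffer_width
    if buffer_width is None:
        xmin, ymin, xmax, ymax = scen_before.geom.bounds
        buffer_width = config.buffer_fraction * max(xmax - xmin, ymax - ymin)
    study_area = _study_area(scen_before, buffer_width)

    # one resistance surface is enough to enumerate candidate focal cells
    ref_surface = resistance.build_resistance_surface(scen_before, profiles[0])
    focal = circuit.sample_focal_nodes(
        study_area, buffer_width, config.n_focal_nodes, ref_surface, seed=config.seed
    )

    maps_before = ensemble_current_maps(scen_before, profiles, focal)
    maps_after = ensemble_current_maps(scen_after, profiles, focal)

    kept_before = consensus.spearman_dedup(maps_before, config.rho_threshold)
    kept_after = consensus.spearman_dedup(maps_after, config.rho_threshold)
    cons_before = consensus.sum_consensus(kept_before, config.rho_threshold)
    cons_after = consensus.sum_consensus(kept_after, config.rho_threshold)
    change = consensus.percent_change(cons_before, cons_after)

    ch = change.values[~np.isnan(change.values)]
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_profiles": len(profiles),
        "buffer_width_m": buffer_width,
        "retained_profiles_before": cons_before.retained_profile_ids,
        "retained_profiles_after": cons_after.retained_profile_ids,
        "n_pairs": getattr(maps_before[0], "n_pairs", None),
        "n_skipped_pairs": getattr(maps_before[0], "n_skipped", 0),
        "change_stats": {
            "mean_pct": float(ch.mean()) if len(ch) else None,
            "min_pct": float(ch.min()) if len(ch) else None,
            "max_pct": float(ch.max()) if len(ch) else None,
            "n_undefined": int(change.mask.sum()),
        },
    }
    result = ImpactResult(
        before=cons_before,
        after=cons_after,
        change=change,
        focal=focal,
        scenario_before=scen_before,
        scenario_after=scen_after,
        landscape=land,
        study_area=study_area,
        report=report,
    )
    if config.output_dir:
        _write_impact(result, config)
    return result


class EmptyCandidateError(RuntimeError):
    """No reforestation candidates survived classification and filtering."""


def run_offset(
    config: RunConfig, impact: ImpactResult, date2: Raster | None = None
) -> OffsetResult:
    """Reforestation prioritisation from an impact-assessment result.

    Deforestation is detected between the earliest land-cover date and
    ``date2`` (default: the before-construction scenario, i.e. the latest
    pre-project land cover).
    """
    land = impact.landscape
    # two-date change detection on elevation-masked land covers
    lc2000 = landcover.apply_elevation_mask(
        land.landcover_2000, land.elevation, config.elevation_threshold
    )
    change_cls = landcover.detect_deforestation(
        lc2000, impact.scenario_before if date2 is None else date2
    )

    extent = box(*impact.scenario_before.geom.bounds)
    cells = prioritise.build_hexgrid(extent)
    cells = prioritise.classify_hexes(cells, change_cls, impact.after.raster)
    deforested = [c for c in cells if c.status == "deforested"]
    if not deforested:
        raise EmptyCandidateError(
            "no deforested hexagons found: nothing to rank "
            f"(cells={len(cells)}, forested={sum(c.status == 'forested' for c in cells)})"
        )
    candidates = prioritise.percentile_filter(deforested, impact.after.raster, config.percentile_q)
    if not candidates:
        raise EmptyCandidateError("percentile filter removed every deforested hexagon")

    patches = prioritise.merge_forest_patches(cells, impact.after.raster)
    if not patches:
        raise EmptyCandidateError("no forested patches: IIC undefined")
    A_L = extent.area

    lost = config.lost_forest_area
    if lost is None:
        n_lost = int(
            (
                (impact.scenario_before.values == landcover.LandCoverClass.FOREST)
                & (impact.scenario_after.values != landcover.LandCoverClass.FOREST)
            ).sum()
        )
        lost = n_lost * impact.scenario_before.geom.cell_area
    scores: dict[float, dict[int, float]] = {}
    for d in config.dispersal_distances:
        scores[d] = {
            c.id: prioritise.variic_add(c, patches, d, A_L) for c in candidates
        }
    ranking = prioritise.rank_candidates(scores, lost)

    rip = prioritise.riparian_subset(candidates, land.rivers)
    rip_ranking = None
    if rip:
        rip_scores = {
            d: {c.id: scores[d][c.id] for c in rip} for d in config.dispersal_distances
        }
        rip_ranking = prioritise.rank_candidates(rip_scores, lost)

    report = {
        "n_hexagons": len(cells),
        "n_deforested": len(deforested),
        "n_candidates": len(candidates),
        "n_riparian_candidates": len(rip),
        "n_patches": len(patches),
        "lost_forest_area_m2": lost,
        "n_selected_per_distance": ranking.n_selected,
        "overlap_summary_pct": {int(k): float(v) for k, v in ranking.summary.items()},
    }
    result = OffsetResult(
        ranking=ranking,
        riparian_ranking=rip_ranking,
        candidates=candidates,
        riparian_candidates=rip,
        patches=patches,
        change_classes=change_cls,
        report=report,
    )
    if config.output_dir:
        _write_offset(result, config)
    return result


# ---------------------------------------------------------------------------
# Artefact writers


def _write_impact(result: ImpactResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(result.before.raster, out / "consensus_before.asc")
    write_ascii_grid(result.after.raster, out / "consensus_after.asc")
    write_ascii_grid(result.change.raster, out / "change_pct.asc")
    write_geojson(result.landscape.footprint, out / "footprint.geojson")
    write_geojson(result.landscape.rivers, out / "rivers.geojson")
    import shapely

    pts = [shapely.Point(x, y) for x, y in result.focal.points]
    write_geojson(
        pts,
        out / "focal_nodes.geojson",
        properties=[{"seed": result.focal.seed}] * len(pts),
    )
    (out / "impact_report.json").write_text(json.dumps(result.report, indent=2))


def _write_offset(result: OffsetResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for d, df in result.ranking.scores.items():
        sel = set(result.ranking.top_n[d])
        for _, r in df.iterrows():
            rows.append(
                {
                    "cell_id": int(r.cell_id),
                    "distance_m": d,
                    "variic_pct": float(r.variic),
                    "selected": int(r.cell_id) in sel,
                }
            )
    pd.DataFrame(rows).to_csv(out / "ranking.csv", index=False)
    write_geojson(
        [c.geometry for c in result.candidates],
        out / "candidates.geojson",
        properties=[
            {"cell_id": c.id, "mean_current": c.mean_current, "riparian": c.riparian}
            for c in result.candidates
        ],
    )
    write_geojson(
        [p.geometry for p in result.patches],
        out / "patches.geojson",
        properties=[{"patch_id": p.id, "attribute": p.attribute} for p in result.patches],
    )
    prioritise.export_conefor(result.patches, result.candidates, out)
    (out / "offset_report.json").write_text(json.dumps(result.report, indent=2))
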