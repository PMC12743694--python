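"""Reforestation offset prioritisation on a 10-ha hexagonal tessellation.

Deforested hexagons (candidates for reforestation) are ranked by how much
adding them back as habitat would raise the Integral Index of Connectivity
(IIC) of the forest patch network:

    IIC = [ Σ_i Σ_j a_i · a_j / (1 + nl_ij) ] / A_L²

where ``a_i`` is the patch attribute (here after-construction current density
divided by patch area), ``nl_ij`` the minimum number of links between patches
i and j in the binary graph that links patches whose edge-to-edge distance is
≤ a dispersal threshold, and ``A_L`` the landscape area. A candidate's score
is varIIC = 100 × (IIC_with − IIC_without) / IIC_without, evaluated one
candidate at a time ("node to add") and at several dispersal thresholds
(default 500 m, 1 km, 2 km).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .grids import Raster
from .landcover import ChangeClass

HEX_CELL_AREA = 100_000.0  # 10 ha in m²
DEFAULT_DISPERSAL_DISTANCES = (500.0, 1000.0, 2000.0)
FOREST_FRACTION_RULE = 0.999  # "100% forested" with rasterisation tolerance
DEFORESTED_FRACTION_RULE = 0.10


def hex_edge_length(cell_area: float = HEX_CELL_AREA) -> float:
    """Edge length s of a regular hexagon with area A = (3√3/2)·s²."""
    if cell_area <= 0:
        raise ValueError(f"cell area must be positive, got {cell_area}")
    return math.sqrt(2.0 * cell_area / (3.0 * math.sqrt(3.0)))


@dataclass
class HexCell:
    """One tessellation cell with its classification and zonal statistics."""

    id: int
    geometry: Polygon
    axial: tuple[int, int]  # (col, row) grid indices for O(1) adjacency
    status: str = "other"  # forested | deforested | other
    forest_fraction: float = 0.0
    deforested_fraction: float = 0.0
    mean_current: float = float("nan")
    current_sum: float = float("nan")
    riparian: bool = False

    @property
    def attribute(self) -> float:
        """Candidate patch attribute: summed current over the hexagon's pixels
        divided by the hexagon area (same scale as HabitatPatch.attribute)."""
        if math.isnan(self.current_sum):
            return 0.0
        return self.current_sum / self.geometry.area


def build_hexgrid(extent: BaseGeometry, cell_area: float = HEX_CELL_AREA) -> list[HexCell]:
    """Regular pointy-top hexagonal tessellation covering ``extent``.

    The grid is anchored at the extent's lower-left corner; cells intersecting
    the extent are retained.
    """
    s = hex_edge_length(cell_area)
    w = math.sqrt(3.0) * s  # horizontal pitch
    vstep = 1.5 * s  # vertical pitch between rows
    xmin, ymin, xmax, ymax = extent.bounds
    # vertex offsets of a pointy-top hexagon centred at origin
    ang = np.deg2rad(np.arange(90, 450, 60))
    verts = np.column_stack([s * np.cos(ang), s * np.sin(ang)])
    cells: list[HexCell] = []
    nrows = int(math.ceil((ymax - ymin) / vstep)) + 2
    ncols = int(math.ceil((xmax - xmin) / w)) + 2
    cid = 0
    for j in range(-1, nrows):
        cy = ymin + j * vstep
        xoff = (w / 2) if (j % 2) else 0.0
        for i in range(-1, ncols):
            cx = xmin + xoff + i * w
            poly = Polygon(np.column_stack([verts[:, 0] + cx, verts[:, 1] + cy]))
            if poly.intersects(extent):
                cells.append(HexCell(id=cid, geometry=poly, axial=(i, j)))
                cid += 1
    return cells


def _hex_neighbours(axial: tuple[int, int]) -> list[tuple[int, int]]:
    """Edge-adjacent cells in the offset (odd-row shifted) hex indexing."""
    i, j = axial
    if j % 2 == 0:
        diag = [(i - 1, j - 1), (i, j - 1), (i - 1, j + 1), (i, j + 1)]
    else:
        diag = [(i, j - 1), (i + 1, j - 1), (i, j + 1), (i + 1, j + 1)]
    return [(i - 1, j), (i + 1, j)] + diag


def classify_hexes(
    cells: list[HexCell], change: Raster, current: Raster | None = None
) -> list[HexCell]:
    """Assign forested / deforested / other status from the change raster.

    A cell is forested iff (within rasterisation tolerance) all its pixels are
    stable forest; otherwise deforested iff ≥ 10% of its pixels are
    deforested; otherwise other. Fractions are computed over raster pixels
    whose centre falls inside the hexagon. When ``current`` is given, the
    cell's mean after-scenario current density is recorded alongside.
    """
    x, y = change.geom.cell_centres()
    pts = shapely.points(np.column_stack([x.ravel(), y.ravel()]))
    tree = shapely.STRtree(pts)
    stable = (change.values == ChangeClass.STABLE_FOREST).ravel()
    defo = (change.values == ChangeClass.DEFORESTED).ravel()
    cur = None if current is None else current.values.ravel()
    for cell in cells:
        idx = tree.query(cell.geometry, predicate="contains")
        n = len(idx)
        if n == 0:
            cell.status = "other"
            continue
        cell.forest_fraction = float(stable[idx].sum()) / n
        cell.deforested_fraction = float(defo[idx].sum()) / n
        if cell.forest_fraction >= FOREST_FRACTION_RULE:
            cell.status = "forested"
        elif cell.deforested_fraction >= DEFORESTED_FRACTION_RULE:
            cell.status = "deforested"
        else:
            cell.status = "other"
        if cur is not None:
            vals = cur[idx]
            vals = vals[~np.isnan(vals)]
            cell.mean_current = float(vals.mean()) if len(vals) else float("nan")
            cell.current_sum = float(vals.sum()) if len(vals) else float("nan")
    return cells


@dataclass
class HabitatPatch:
    """A merged block of adjacent forested hexagons, a node of the IIC graph."""

    id: int
    geometry: BaseGeometry
    area: float
    attribute: float  # summed current over patch pixels / patch area
    member_cell_ids: list[int] = field(default_factory=list)


def merge_forest_patches(
    cells: list[HexCell], current: Raster | None = None
) -> list[HabitatPatch]:
    """Union edge-adjacent forested hexagons into habitat patches.

    Deforested cells are never merged. The patch attribute is the summed
    after-scenario current over the patch's pixels divided by the patch area
    (i.e. mean current density per m²); zero if no current map is supplied.
    """
    forested = [c for c in cells if c.status == "forested"]
    by_axial = {c.axial: k for k, c in enumerate(forested)}
    n = len(forested)
    if n == 0:
        return []
    rows, cols = [], []
    for k, c in enumerate(forested):
        for nb in _hex_neighbours(c.axial):
            m = by_axial.get(nb)
            if m is not None:
                rows.append(k)
                cols.append(m)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    patches = []
    for comp in range(n_comp):
        members = [forested[k] for k in np.nonzero(labels == comp)[0]]
        geom = shapely.unary_union([c.geometry for c in members])
        area = geom.area
        attr = 0.0
        if current is not None:
            attr = _summed_current(geom, current) / area
        patches.append(
            HabitatPatch(
                id=comp,
                geometry=geom,
                area=area,
                attribute=attr,
                member_cell_ids=[c.id for c in members],
            )
        )
    return patches


def _summed_current(geom: BaseGeometry, current: Raster) -> float:
    """Sum of current over raster pixels whose centre lies inside ``geom``."""
    xmin, ymin, xmax, ymax = geom.bounds
    g = current.geom
    c0 = max(0, int((xmin - g.x0) / g.cell) - 1)
    c1 = min(g.ncols, int((xmax - g.x0) / g.cell) + 2)
    r0 = max(0, int((g.y1 - ymax) / g.cell) - 1)
    r1 = min(g.nrows, int((g.y1 - ymin) / g.cell) + 2)
    if c0 >= c1 or r0 >= r1:
        return 0.0
    xs = g.x0 + (np.arange(c0, c1) + 0.5) * g.cell
    ys = g.y1 - (np.arange(r0, r1) + 0.5) * g.cell
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(xx.shape)
    sub = current.values[r0:r1, c0:c1]
    return float(np.nansum(np.where(inside, sub, 0.0)))


def percentile_filter(
    deforested_cells: list[HexCell], current: Raster, q: float = 20.0
) -> list[HexCell]:
    """Retain deforested cells whose mean current exceeds the q-th percentile.

    The percentile (linear interpolation) is taken over the deforested cells'
    own mean after-scenario current densities; retention is strict (>).
    """
    if not deforested_cells:
        raise ValueError("no deforested cells to filter")
    for cell in deforested_cells:
        if math.isnan(cell.mean_current):
            cell.mean_current = _summed_current(cell.geometry, current) / max(
                1, _pixel_count(cell.geometry, current)
            )
    means = np.array([c.mean_current for c in deforested_cells])
    cutoff = float(np.percentile(means, q))
    kept = [c for c in deforested_cells if c.mean_current > cutoff]
    if not kept:
        import warnings

        warnings.warn(
            "percentile filter retained no cells (degenerate current distribution)",
            stacklevel=2,
        )
    return kept


def _pixel_count(geom: BaseGeometry, raster: Raster) -> int:
    xmin, ymin, xmax, ymax = geom.bounds
    g = raster.geom
    c0 = max(0, int((xmin - g.x0) / g.cell) - 1)
    c1 = min(g.ncols, int((xmax - g.x0) / g.cell) + 2)
    r0 = max(0, int((g.y1 - ymax) / g.cell) - 1)
    r1 = min(g.nrows, int((g.y1 - ymin) / g.cell) + 2)
    if c0 >= c1 or r0 >= r1:
        return 0
    xs = g.x0 + (np.arange(c0, c1) + 0.5) * g.cell
    ys = g.y1 - (np.arange(r0, r1) + 0.5) * g.cell
    xx, yy = np.meshgrid(xs, ys)
    return int(shapely.contains_xy(geom, xx.ravel(), yy.ravel()).sum())


def interpatch_distance(p1: BaseGeometry, p2: BaseGeometry) -> float:
    """Minimum edge-to-edge Euclidean distance; 0 for touching/overlapping."""
    return float(p1.distance(p2))


def _link_counts(geoms: list[BaseGeometry], d: float) -> np.ndarray:
    """Matrix of minimum link counts nl_ij on the ≤ d threshold graph.

    Entries are np.inf between different components; the diagonal is 0.
    """
    n = len(geoms)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if geoms[i].distance(geoms[j]) <= d:
                rows.append(i)
                cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    nl = shortest_path(adj, method="D", directed=False, unweighted=True)
    return nl


def compute_iic(patches: list[HabitatPatch], d: float, A_L: float) -> float:
    """Integral Index of Connectivity of the patch set at threshold ``d``."""
    if not patches:
        raise ValueError("need at least one patch")
    if d <= 0:
        raise ValueError(f"dispersal threshold must be positive, got {d}")
    if A_L <= 0:
        raise ValueError(f"landscape area must be positive, got {A_L}")
    a = np.array([p.attribute for p in patches])
    nl = _link_counts([p.geometry for p in patches], d)
    with np.errstate(divide="ignore"):
        weight = 1.0 / (1.0 + nl)  # inf -> 0 contribution
    weight[np.isinf(nl)] = 0.0
    numerator = float(a @ weight @ a)
    return numerator / (A_L * A_L)


def variic_add(
    candidate: HexCell, patches: list[HabitatPatch], d: float, A_L: float,
    candidate_attribute: float | None = None,
) -> float:
    """Percent IIC gain from reforesting one candidate hexagon.

    The candidate joins the patch graph as a new node with attribute equal to
    its after-scenario current divided by its area (unless overridden); links
    and link counts are fully recomputed with the candidate present.
    """
    base = compute_iic(patches, d, A_L)
    if base == 0:
        raise ValueError("base IIC is 0: degenerate landscape, varIIC undefined")
    attr = candidate.attribute if candidate_attribute is None else candidate_attribute
    cand_patch = HabitatPatch(
        id=-1, geometry=candidate.geometry, area=candidate.geometry.area, attribute=attr
    )
    with_cand = compute_iic(patches + [cand_patch], d, A_L)
    return 100.0 * (with_cand - base) / base


@dataclass
class PriorityRanking:
    """Per-distance varIIC rankings, top-N selections and overlap summary."""

    scores: dict[float, pd.DataFrame]  # distance -> (cell_id, variic) sorted desc
    top_n: dict[float, list[int]]
    n_selected: int
    overlap: pd.Series  # cell_id -> number of distances at which selected
    summary: pd.Series  # overlap category (1..k) -> percentage of selected cells


def rank_candidates(
    scores: dict[float, dict[int, float]],
    lost_forest_area: float,
    cell_area: float = HEX_CELL_AREA,
) -> PriorityRanking:
    """Select the top-N candidates per dispersal distance and summarise overlap.

    N = lost forest area / cell area, rounded half-up (e.g. 8 km² of loss at
    10-ha cells → 80). Ties in varIIC break toward the smaller candidate id.
    """
    n_sel = int(math.floor(lost_forest_area / cell_area + 0.5))
    if n_sel <= 0:
        raise ValueError("lost forest area implies a non-positive selection size")
    per_distance: dict[float, pd.DataFrame] = {}
    top: dict[float, list[int]] = {}
    for d, sc in scores.items():
        df = pd.DataFrame(
            sorted(sc.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["cell_id", "variic"],
        )
        per_distance[d] = df
        top[d] = df["cell_id"].head(n_sel).tolist()
    all_selected = sorted(set().union(*top.values())) if top else []
    counts = pd.Series(
        {cid: sum(cid in t for t in top.values()) for cid in all_selected}, dtype=int
    )
    k = len(scores)
    if len(counts):
        summary = (
            counts.value_counts().reindex(range(1, k + 1), fill_value=0)
            / len(counts)
            * 100.0
        )
    else:
        summary = pd.Series(0.0, index=range(1, k + 1))
    return PriorityRanking(
        scores=per_distance, top_n=top, n_selected=n_sel, overlap=counts, summary=summary
    )


def riparian_subset(cells: list[HexCell], rivers: list[BaseGeometry]) -> list[HexCell]:
    """Flag and return cells whose hexagon intersects any river geometry."""
    for cell in cells:
        cell.riparian = any(cell.geometry.intersects(r) for r in rivers)
    return [c for c in cells if c.riparian]


# ---------------------------------------------------------------------------
# Conefor-format export (plain-text node and distance files)


def export_conefor(
    patches: list[HabitatPatch],
    candidates: list[HexCell],
    out_dir: str | Path,
    prefix: str = "conefor",
) -> tuple[Path, Path]:
    """Write Conefor-style node (id, attribute) and distance (id1, id2, dist)
    files so IIC/varIIC can be verified externally. Candidate hexagons get ids
    offset above the patch ids."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    offset = (max(p.id for p in patches) + 1) if patches else 0
    nodes: list[tuple[int, float, BaseGeometry]] = [
        (p.id, p.attribute, p.geometry) for p in patches
    ]
    for c in candidates:
        nodes.append((offset + c.id, c.attribute, c.geometry))
    node_path = out_dir / f"{prefix}_nodes.txt"
    dist_path = out_dir / f"{prefix}_distances.txt"
    with open(node_path, "w") as fh:
        for nid, attr, _ in nodes:
            fh.write(f"{nid}\t{attr!r}\n")
    with open(dist_path, "w") as fh:
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                dist = nodes[i][2].distance(nodes[j][2])
                fh.write(f"{nodes[i][0]}\t{nodes[j][0]}\t{dist!r}\n")
    return node_path, dist_path


def read_conefor(node_path: str | Path, dist_path: str | Path):
    """Round-trip reader for the exported node/distance files."""
    nodes = {}
    with open(node_path) as fh:
        for line in fh:
            nid, attr = line.split()
            nodes[int(nid)] = float(attr)
    dists = {}
    with open(dist_path) as fh:
        for line in fh:
            i, j, dv = line.split()
            dists[(int(i), int(j))] = float(dv)
    return nodes, dists


def iic_from_conefor(nodes: dict[int, float], dists: dict, d: float, A_L: float) -> float:
    """IIC recomputed purely from exported node/distance tables (oracle path)."""
    ids = sorted(nodes)
    n = len(ids)
    pos = {nid: k for k, nid in enumerate(ids)}
    rows, cols = [], []
    for (i, j), dist in dists.items():
        if dist <= d:
            rows.append(pos[i])
            cols.append(pos[j])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    nl = shortest_path(adj, directed=False, unweighted=True)
    a = np.array([nodes[i] for i in ids])
    weight = 1.0 / (1.0 + nl)
    weight[np.isinf(nl)] = 0.0
    return float(a @ weight @ a) / (A_L * A_L)
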