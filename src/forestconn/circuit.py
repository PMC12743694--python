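"""Circuit-theory connectivity on raster resistance surfaces.

The landscape raster is an electrical network: every in-extent cell is a
node, every pair of 8-neighbour cells a resistor. Injecting one ampere at a
source focal node and extracting it at a ground node yields per-edge currents
(by solving the graph-Laplacian system ``L v = b``); the per-cell current
density — half the sum of absolute currents on a cell's incident edges — is a
proxy for expected animal movement through that cell. Accumulating over all
focal-node pairs ("pairwise mode") produces a cumulative current-density map.

Conventions follow standard raster circuit modelling: the conductance of an
orthogonal edge is the reciprocal of the mean resistance of its two cells,
and diagonal edges are down-weighted by √2 for the longer traversal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import shapely
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu
from shapely.geometry.base import BaseGeometry

from .grids import Raster

logger = logging.getLogger(__name__)

#: residual tolerance for the Laplacian solves (relative to unit injection)
SOLVER_TOL = 1e-10


class EmptyGraphError(ValueError):
    """The resistance raster has no in-extent cells."""


class ConnectivityError(ValueError):
    """Source and ground fall in different connected components."""


class FocalSamplingError(ValueError):
    """The buffer ring contains fewer candidate cells than requested nodes."""


@dataclass
class ConductanceGraph:
    """Undirected conductance network over in-extent raster cells."""

    node_of_cell: np.ndarray  # (nrows, ncols) int32, -1 outside extent
    cells: np.ndarray  # (n_nodes, 2) row, col of each node
    edge_i: np.ndarray  # (n_edges,) node indices, edge_i < edge_j
    edge_j: np.ndarray
    conductance: np.ndarray  # (n_edges,) > 0
    raster: Raster = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    @property
    def n_edges(self) -> int:
        return len(self.conductance)

    def laplacian(self) -> csc_matrix:
        i, j, g = self.edge_i, self.edge_j, self.conductance
        n = self.n_nodes
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([-g, -g, g, g])
        return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()

    def components(self) -> np.ndarray:
        i, j = self.edge_i, self.edge_j
        n = self.n_nodes
        adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        return labels


def build_network(resistance: Raster) -> ConductanceGraph:
    """8-neighbour conductance graph from a resistance surface.

    Orthogonal neighbours ``i, j`` get conductance ``1 / ((r_i + r_j) / 2)``;
    diagonal neighbours get that value divided by √2. NoData cells are
    excluded from the graph.
    """
    r = np.asarray(resistance.values, dtype=float)
    valid = resistance.valid_mask()
    if not valid.any():
        raise EmptyGraphError("resistance raster has no in-extent cells")
    if np.any(r[valid] <= 0):
        raise ValueError("resistances must be positive")

    nrows, ncols = r.shape
    node_of_cell = np.full((nrows, ncols), -1, dtype=np.int32)
    rows, cols = np.nonzero(valid)
    node_of_cell[rows, cols] = np.arange(len(rows), dtype=np.int32)
    cells = np.column_stack([rows, cols])

    # offsets covering each undirected 8-neighbour pair once
    offsets = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    ei, ej, gg = [], [], []
    for dr, dc, length in offsets:
        r0s = slice(max(0, -dr), nrows - max(0, dr))
        c0s = slice(max(0, -dc), ncols - max(0, dc))
        r1s = slice(max(0, dr), nrows - max(0, -dr))
        c1s = slice(max(0, dc), ncols - max(0, -dc))
        a = node_of_cell[r0s, c0s]
        b = node_of_cell[r1s, c1s]
        ra = r[r0s, c0s]
        rb = r[r1s, c1s]
        ok = (a >= 0) & (b >= 0)
        cond = 1.0 / ((ra[ok] + rb[ok]) / 2.0) / length
        ei.append(a[ok])
        ej.append(b[ok])
        gg.append(cond)
    edge_i = np.concatenate(ei).astype(np.int64)
    edge_j = np.concatenate(ej).astype(np.int64)
    conductance = np.concatenate(gg)
    swap = edge_i > edge_j
    edge_i[swap], edge_j[swap] = edge_j[swap], edge_i[swap]
    return ConductanceGraph(node_of_cell, cells, edge_i, edge_j, conductance, resistance)


@dataclass
class FocalNodeSet:
    """Focal cells sampled in the buffer ring around the study area."""

    points: np.ndarray  # (n, 2) x, y cell-centre coordinates
    node_ids: np.ndarray  # (n,) graph/cell linear indices (row, col packed)
    cells: np.ndarray  # (n, 2) row, col
    buffer_width: float
    seed: int


def sample_focal_nodes(
    extent: BaseGeometry,
    buffer_width: float,
    n: int,
    resistance: Raster,
    seed: int,
) -> FocalNodeSet:
    """Sample ``n`` distinct focal cells uniformly in the buffer ring.

    The ring is the area between the study-area boundary (``extent``) and the
    boundary dilated by ``buffer_width``. Candidate cells are in-extent
    (non-NoData) raster cells whose centre falls in the ring.
    """
    if n < 2:
        raise ValueError("need at least 2 focal nodes")
    ring = extent.buffer(buffer_width).difference(extent)
    if ring.is_empty:
        raise FocalSamplingError("buffer ring is empty")
    x, y = resistance.geom.cell_centres()
    flat_x, flat_y = x.ravel(), y.ravel()
    in_ring = shapely.contains_xy(ring, flat_x, flat_y)
    candidates = np.nonzero(in_ring & resistance.valid_mask().ravel())[0]
    if len(candidates) < n:
        raise FocalSamplingError(
            f"buffer ring holds {len(candidates)} candidate cells, need {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(candidates, size=n, replace=False))
    rows, cols = np.unravel_index(chosen, resistance.shape)
    return FocalNodeSet(
        points=np.column_stack([flat_x[chosen], flat_y[chosen]]),
        node_ids=chosen,
        cells=np.column_stack([rows, cols]),
        buffer_width=buffer_width,
        seed=seed,
    )


class PairSolver:
    """Solves unit-current injections on one conductance graph.

    One sparse LU factorisation per connected component is built lazily and
    reused across all focal pairs; each pair then costs two triangular solves.
    """

    def __init__(self, graph: ConductanceGraph):
        self.graph = graph
        self.labels = graph.components()
        self._lap = graph.laplacian()
        self._factor: dict[int, tuple] = {}

    def _component_factor(self, label: int):
        if label not in self._factor:
            members = np.nonzero(self.labels == label)[0]
            if len(members) < 2:
                raise ConnectivityError("component has fewer than 2 nodes")
            sub = self._lap[np.ix_(members, members)].tocsc()
            # ground the last member to make the Laplacian nonsingular
            reduced = sub[:-1, :-1].tocsc()
            self._factor[label] = (members, splu(reduced))
        return self._factor[label]

    def solve_pair(self, source: int, ground: int) -> tuple[np.ndarray, np.ndarray]:
        """Voltages (ground fixed at 0) and signed per-edge currents for one pair.

        Current of 1 enters at ``source`` and leaves at ``ground``. Edge
        current sign is positive when flow goes from the lower- to the
        higher-indexed endpoint of the edge.
        """
        if source == ground:
            raise ValueError("source and ground must differ")
        if self.labels[source] != self.labels[ground]:
            raise ConnectivityError(
                f"nodes {source} and {ground} lie in different components"
            )
        members, lu = self._component_factor(self.labels[source])
        pos = {int(m): k for k, m in enumerate(members)}
        b = np.zeros(len(members) - 1)
        ps, pg = pos[source], pos[ground]
        if ps < len(b):
            b[ps] = 1.0
        if pg < len(b):
            b[pg] -= 1.0
        v_red = lu.solve(b)
        v_comp = np.append(v_red, 0.0)
        v_comp -= v_comp[pg]  # fix ground voltage to exactly 0
        voltages = np.full(self.graph.n_nodes, np.nan)
        voltages[members] = v_comp
        dv = voltages[self.graph.edge_i] - voltages[self.graph.edge_j]
        currents = np.where(np.isnan(dv), 0.0, self.graph.conductance * np.nan_to_num(dv))
        return voltages, currents

    def node_currents(self, source: int, ground: int) -> np.ndarray:
        """Per-node current density for one pair.

        Half the sum of absolute incident edge currents at every node, except
        at the two focal nodes where it is the injected current (1).
        """
        _, currents = self.solve_pair(source, ground)
        node_cur = np.zeros(self.graph.n_nodes)
        np.add.at(node_cur, self.graph.edge_i, np.abs(currents))
        np.add.at(node_cur, self.graph.edge_j, np.abs(currents))
        node_cur *= 0.5
        node_cur[source] = 1.0
        node_cur[ground] = 1.0
        return node_cur


def cumulative_current(graph: ConductanceGraph, nodes: FocalNodeSet) -> Raster:
    """Cumulative current-density map over all unordered focal pairs.

    Pairs whose endpoints lie in different components are skipped with a
    warning. The result raster carries ``n_pairs`` (solved pair count) and the
    source surface's ``profile_id`` when present.
    """
    solver = PairSolver(graph)
    focal = [int(graph.node_of_cell[r, c]) for r, c in nodes.cells]
    if any(f < 0 for f in focal):
        raise ValueError("a focal cell is outside the graph extent")
    total = np.zeros(graph.n_nodes)
    n_pairs = 0
    n_skipped = 0
    for a, b in combinations(sorted(focal), 2):
        if solver.labels[a] != solver.labels[b]:
            n_skipped += 1
            continue
        total += solver.node_currents(a, b)
        n_pairs += 1
    if n_skipped:
        logger.warning("skipped %d focal pair(s) spanning disconnected components", n_skipped)
    if n_pairs == 0:
        raise ConnectivityError("no focal pair lies within a single component")
    vals = np.full(graph.raster.shape, np.nan)
    vals[graph.cells[:, 0], graph.cells[:, 1]] = total
    out = Raster(vals, graph.raster.geom, crs=graph.raster.crs, nodata=np.nan)
    out.n_pairs = n_pairs
    out.n_skipped = n_skipped
    out.profile_id = getattr(graph.raster, "profile_id", None)
    return out


def buffer_width_from_extent(extent: BaseGeometry, fraction: float = 0.2) -> float:
    """Buffer width as a fraction of the maximum extent length (default 20%)."""
    xmin, ymin, xmax, ymax = extent.bounds
    return fraction * max(xmax - xmin, ymax - ymin)
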