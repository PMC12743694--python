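"""Hex tessellation, patch merging, IIC/varIIC against brute-force oracles,
candidate filtering, ranking and riparian flagging."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point, box

from forestconn.grids import GridGeometry, Raster
from forestconn.landcover import ChangeClass
from forestconn.prioritise import (
    HEX_CELL_AREA,
    HabitatPatch,
    HexCell,
    _hex_neighbours,
    build_hexgrid,
    classify_hexes,
    compute_iic,
    export_conefor,
    hex_edge_length,
    iic_from_conefor,
    interpatch_distance,
    merge_forest_patches,
    percentile_filter,
    rank_candidates,
    read_conefor,
    riparian_subset,
    variic_add,
)
from tests.conftest import make_raster

# ---------------------------------------------------------------------------
# brute-force oracles


def iic_oracle(attrs, geoms, d, A_L):
    """Independent IIC: explicit double loop over pairs with BFS link counts."""
    n = len(attrs)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if geoms[i].distance(geoms[j]) <= d:
                adj[i].append(j)
                adj[j].append(i)

    def bfs(src):
        dist = [math.inf] * n
        dist[src] = 0
        queue = [src]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] == math.inf:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            queue = nxt
        return dist

    total = 0.0
    for i in range(n):
        dist = bfs(i)
        for j in range(n):
            if dist[j] != math.inf:
                total += attrs[i] * attrs[j] / (1.0 + dist[j])
    return total / (A_L * A_L)


def random_patchset(rng, n_max=12):
    n = rng.integers(1, n_max)
    patches = []
    for k in range(n):
        cx, cy = rng.uniform(0, 5000, 2)
        half = rng.uniform(20, 300)
        geom = box(cx - half, cy - half, cx + half, cy + half)
        patches.append(HabitatPatch(id=k, geometry=geom, area=geom.area, attribute=rng.uniform(0, 5)))
    return patches


# ---------------------------------------------------------------------------
# tessellation


class TestHexGrid:
    def test_edge_length_closed_form(self):
        s = hex_edge_length(HEX_CELL_AREA)
        assert s == pytest.approx(math.sqrt(2 * HEX_CELL_AREA / (3 * math.sqrt(3))))
        assert s == pytest.approx(196.19, abs=0.01)

    def test_cells_have_10ha_area(self):
        cells = build_hexgrid(box(0, 0, 1500, 1500))
        for c in cells[:5]:
            assert abs(c.geometry.area - HEX_CELL_AREA) / HEX_CELL_AREA < 1e-6

    def test_interiors_pairwise_disjoint(self):
        cells = build_hexgrid(box(0, 0, 1200, 1200))
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                inter = cells[i].geometry.intersection(cells[j].geometry)
                assert inter.area < 1e-6

    def test_union_covers_extent(self):
        extent = box(0, 0, 1500, 1500)
        cells = build_hexgrid(extent)
        gap = extent.difference(shapely.unary_union([c.geometry for c in cells]))
        assert gap.area < 1e-6

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            hex_edge_length(0.0)

    def test_axial_neighbours_are_the_six_adjacent_cells(self):
        cells = build_hexgrid(box(0, 0, 2000, 2000))
        by_axial = {c.axial: c for c in cells}
        probe = next(
            c for c in cells if all(nb in by_axial for nb in _hex_neighbours(c.axial))
        )
        nbs = [by_axial[nb] for nb in _hex_neighbours(probe.axial)]
        assert len(nbs) == 6
        pitch = math.sqrt(3) * hex_edge_length()
        for nb in nbs:
            d = probe.geometry.centroid.distance(nb.geometry.centroid)
            assert d == pytest.approx(pitch, rel=1e-9)
            assert probe.geometry.distance(nb.geometry) < 1e-6


# ---------------------------------------------------------------------------
# classification and merging


def change_raster_from_masks(stable, deforested, cell=60.0):
    vals = np.full(stable.shape, ChangeClass.OTHER, dtype=np.uint8)
    vals[stable] = ChangeClass.STABLE_FOREST
    vals[deforested] = ChangeClass.DEFORESTED
    return make_raster(vals, cell=cell, nodata=255)


class TestClassifyHexes:
    def make_cells(self, n=1, status_geom=None):
        return build_hexgrid(box(0, 0, 1000, 1000))

    def test_fully_forested_hexagon(self):
        stable = np.ones((30, 30), bool)
        change = change_raster_from_masks(stable, np.zeros_like(stable))
        cells = classify_hexes(build_hexgrid(box(0, 0, 1800, 1800)), change)
        inner = [c for c in cells if box(200, 200, 1600, 1600).contains(c.geometry)]
        assert inner and all(c.status == "forested" for c in inner)

    def test_partially_deforested_hexagon(self):
        rng = np.random.default_rng(0)
        stable = np.zeros((30, 30), bool)
        deforested = rng.random((30, 30)) < 0.5  # ~50% >> 10% rule
        change = change_raster_from_masks(stable, deforested)
        cells = classify_hexes(build_hexgrid(box(0, 0, 1800, 1800)), change)
        inner = [c for c in cells if box(200, 200, 1600, 1600).contains(c.geometry)]
        assert inner and all(c.status == "deforested" for c in inner)

    def test_below_both_rules_is_other(self):
        # deforested fraction ~5%, forest ~80%: fails both rules
        rng = np.random.default_rng(1)
        u = rng.random((40, 40))
        deforested = u < 0.05
        stable = (u >= 0.05) & (u < 0.85)
        change = change_raster_from_masks(stable, deforested)
        cells = classify_hexes(build_hexgrid(box(0, 0, 2400, 2400)), change)
        inner = [c for c in cells if box(300, 300, 2100, 2100).contains(c.geometry)]
        assert inner
        fuzzy = [c for c in inner if 0.01 < c.deforested_fraction < 0.10 and c.forest_fraction < 0.999]
        assert fuzzy and all(c.status == "other" for c in fuzzy)

    def test_mean_current_recorded(self):
        stable = np.ones((30, 30), bool)
        change = change_raster_from_masks(stable, np.zeros_like(stable))
        current = make_raster(np.full((30, 30), 2.5))
        cells = classify_hexes(build_hexgrid(box(0, 0, 1800, 1800)), change, current)
        inner = [c for c in cells if box(200, 200, 1600, 1600).contains(c.geometry)]
        for c in inner:
            assert c.mean_current == pytest.approx(2.5)


class TestMergePatches:
    def grid_with_statuses(self, statuses):
        cells = build_hexgrid(box(0, 0, 2500, 2500))
        by_axial = {c.axial: c for c in cells}
        for ax, st in statuses.items():
            by_axial[ax].status = st
        return cells, by_axial

    def test_two_adjacent_forested_hexes_merge(self):
        cells, by_axial = self.grid_with_statuses({})
        probe = cells[len(cells) // 2]
        nb = next(n for n in _hex_neighbours(probe.axial) if n in by_axial)
        probe.status = "forested"
        by_axial[nb].status = "forested"
        patches = merge_forest_patches(cells)
        assert len(patches) == 1
        assert patches[0].area == pytest.approx(2 * HEX_CELL_AREA, rel=1e-6)

    def test_separated_hexes_stay_apart(self):
        cells, by_axial = self.grid_with_statuses({})
        probe = cells[len(cells) // 2]
        probe.status = "forested"
        # pick a far-away cell
        far = max(cells, key=lambda c: probe.geometry.distance(c.geometry))
        far.status = "forested"
        assert len(merge_forest_patches(cells)) == 2

    def test_component_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(4)
        cells, by_axial = self.grid_with_statuses({})
        forested = [c for c in cells if rng.random() < 0.4]
        for c in forested:
            c.status = "forested"
        patches = merge_forest_patches(cells)
        # flood fill over the axial adjacency of forested cells
        axials = {c.axial for c in forested}
        seen, n_comp = set(), 0
        for ax in axials:
            if ax in seen:
                continue
            n_comp += 1
            stack = [ax]
            seen.add(ax)
            while stack:
                cur = stack.pop()
                for nb in _hex_neighbours(cur):
                    if nb in axials and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        assert len(patches) == n_comp


# ---------------------------------------------------------------------------
# candidate filtering, distances, IIC


class TestPercentileFilter:
    def make_cells(self, currents):
        cells = []
        for k, cur in enumerate(currents):
            c = HexCell(id=k, geometry=box(k * 10, 0, k * 10 + 5, 5), axial=(k, 0), status="deforested")
            c.mean_current = cur
            c.current_sum = cur
            cells.append(c)
        return cells

    def test_linear_interpolation_percentile(self):
        cells = self.make_cells(range(1, 11))
        current = make_raster(np.ones((2, 2)))
        kept = percentile_filter(cells, current, q=20.0)
        # 20th percentile of 1..10 is 2.8; strictly above leaves 3..10
        assert [c.mean_current for c in kept] == list(range(3, 11))

    def test_degenerate_equal_currents_warns_and_empties(self):
        cells = self.make_cells([2.0] * 6)
        with pytest.warns(UserWarning):
            kept = percentile_filter(cells, make_raster(np.ones((2, 2))), q=20.0)
        assert kept == []

    def test_q_zero_drops_only_minima(self):
        cells = self.make_cells([1.0, 1.0, 2.0, 3.0])
        kept = percentile_filter(cells, make_raster(np.ones((2, 2))), q=0.0)
        assert [c.mean_current for c in kept] == [2.0, 3.0]


class TestInterpatchDistance:
    def test_touching_is_zero(self):
        assert interpatch_distance(box(0, 0, 1, 1), box(1, 0, 2, 1)) == 0.0

    def test_two_unit_squares_5m_apart(self):
        assert interpatch_distance(box(0, 0, 1, 1), box(6, 0, 7, 1)) == pytest.approx(5.0)

    def test_matches_densified_vertex_oracle(self):
        from scipy.spatial.distance import cdist

        rng = np.random.default_rng(7)
        for _ in range(20):
            g1 = Point(rng.uniform(0, 100, 2)).buffer(rng.uniform(1, 10), quad_segs=8)
            g2 = Point(rng.uniform(150, 250, 2)).buffer(rng.uniform(1, 10), quad_segs=8)
            d = interpatch_distance(g1, g2)
            b1 = np.asarray(g1.exterior.segmentize(0.05).coords)
            b2 = np.asarray(g2.exterior.segmentize(0.05).coords)
            oracle = cdist(b1, b2).min()
            assert abs(d - oracle) < 0.1


class TestIIC:
    def test_single_patch(self):
        p = HabitatPatch(0, box(0, 0, 1, 1), 1.0, 4.0)
        assert compute_iic([p], d=1.0, A_L=100.0) == pytest.approx(16.0 / 10_000)

    def test_three_patch_chain_hand_value(self):
        g1, g2, g3 = box(0, 0, 1, 1), box(5, 0, 6, 1), box(10, 0, 11, 1)
        patches = [
            HabitatPatch(0, g1, 1.0, 2.0),
            HabitatPatch(1, g2, 1.0, 1.0),
            HabitatPatch(2, g3, 1.0, 3.0),
        ]
        # links 1-2 and 2-3 only (gaps of 4 <= d < 8)
        assert compute_iic(patches, d=4.5, A_L=100.0) == pytest.approx(0.0023)

    def test_disconnected_pair(self):
        p1 = HabitatPatch(0, box(0, 0, 1, 1), 1.0, 2.0)
        p2 = HabitatPatch(1, box(100, 0, 101, 1), 1.0, 3.0)
        assert compute_iic([p1, p2], d=5.0, A_L=10.0) == pytest.approx((4 + 9) / 100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        patches = random_patchset(rng)
        attrs = [p.attribute for p in patches]
        geoms = [p.geometry for p in patches]
        for d in (500.0, 1000.0, 2000.0):
            ours = compute_iic(patches, d, A_L=25_000_000.0)
            oracle = iic_oracle(attrs, geoms, d, A_L=25_000_000.0)
            assert ours == pytest.approx(oracle, rel=1e-12, abs=1e-300)

    @pytest.mark.parametrize("seed", range(5))
    def test_nondecreasing_in_threshold(self, seed):
        rng = np.random.default_rng(100 + seed)
        patches = random_patchset(rng)
        vals = [compute_iic(patches, d, 1e6) for d in (250, 500, 1000, 2000, 4000)]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_invalid_args_rejected(self):
        p = HabitatPatch(0, box(0, 0, 1, 1), 1.0, 1.0)
        with pytest.raises(ValueError):
            compute_iic([], 1.0, 1.0)
        with pytest.raises(ValueError):
            compute_iic([p], -1.0, 1.0)
        with pytest.raises(ValueError):
            compute_iic([p], 1.0, 0.0)


class TestVarIIC:
    def candidate(self, geom, current_sum):
        c = HexCell(id=0, geometry=geom, axial=(0, 0), status="deforested")
        c.current_sum = current_sum
        c.mean_current = current_sum
        return c

    def test_isolated_zero_attribute_candidate_scores_zero(self):
        patches = [HabitatPatch(0, box(0, 0, 10, 10), 100.0, 2.0)]
        cand = self.candidate(box(10_000, 10_000, 10_010, 10_010), 0.0)
        assert variic_add(cand, patches, d=500.0, A_L=1e6) == pytest.approx(0.0)

    def test_isolated_candidate_closed_form(self):
        patches = [
            HabitatPatch(0, box(0, 0, 10, 10), 100.0, 2.0),
            HabitatPatch(1, box(100, 0, 110, 10), 100.0, 1.0),
        ]
        A_L = 1e6
        base = compute_iic(patches, 500.0, A_L)
        geom = box(50_000, 50_000, 50_010, 50_010)
        a = 3.7
        cand = self.candidate(geom, a * geom.area)
        expect = 100.0 * (a * a / (A_L * A_L)) / base
        assert variic_add(cand, patches, 500.0, A_L) == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_always_nonnegative_and_matches_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        patches = random_patchset(rng)
        geom = Point(rng.uniform(0, 5000, 2)).buffer(150, quad_segs=4)
        cand = self.candidate(geom, rng.uniform(0, 5) * geom.area)
        for d in (500.0, 2000.0):
            v = variic_add(cand, patches, d, A_L=25_000_000.0)
            assert v >= -1e-12
            base = iic_oracle(
                [p.attribute for p in patches], [p.geometry for p in patches], d, 25_000_000.0
            )
            withc = iic_oracle(
                [p.attribute for p in patches] + [cand.attribute],
                [p.geometry for p in patches] + [geom],
                d,
                25_000_000.0,
            )
            assert v == pytest.approx(100 * (withc - base) / base, rel=1e-9, abs=1e-12)

    def test_degenerate_zero_base_rejected(self):
        patches = [HabitatPatch(0, box(0, 0, 1, 1), 1.0, 0.0)]
        cand = self.candidate(box(5, 5, 6, 6), 1.0)
        with pytest.raises(ValueError):
            variic_add(cand, patches, 500.0, 1e6)


class TestRanking:
    def test_eight_km2_loss_selects_80(self):
        scores = {d: {i: float(i) for i in range(200)} for d in (500.0, 1000.0, 2000.0)}
        ranking = rank_candidates(scores, lost_forest_area=8e6)
        assert ranking.n_selected == 80
        for d in scores:
            assert len(ranking.top_n[d]) == 80

    def test_identical_scores_full_overlap(self):
        scores = {d: {i: float(100 - i) for i in range(100)} for d in (500.0, 1000.0, 2000.0)}
        ranking = rank_candidates(scores, lost_forest_area=2e6)  # N = 20
        assert ranking.summary[3] == pytest.approx(100.0)
        assert ranking.summary[1] == 0.0

    def test_disjoint_top_sets_no_overlap(self):
        scores = {
            500.0: {i: (10.0 if i < 10 else 0.0) for i in range(30)},
            1000.0: {i: (10.0 if 10 <= i < 20 else 0.0) for i in range(30)},
        }
        ranking = rank_candidates(scores, lost_forest_area=1e6)  # N = 10
        assert ranking.summary[1] == pytest.approx(100.0)
        assert ranking.summary[2] == 0.0

    def test_ties_break_to_ascending_id(self):
        scores = {500.0: {5: 1.0, 2: 1.0, 9: 1.0, 1: 2.0}}
        ranking = rank_candidates(scores, lost_forest_area=2 * HEX_CELL_AREA)
        assert ranking.top_n[500.0] == [1, 2]

    def test_nonpositive_selection_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates({500.0: {0: 1.0}}, lost_forest_area=0.0)

    def test_summary_percentages_sum_to_100(self):
        rng = np.random.default_rng(9)
        scores = {d: {i: float(rng.random()) for i in range(60)} for d in (500.0, 1000.0, 2000.0)}
        ranking = rank_candidates(scores, lost_forest_area=15 * HEX_CELL_AREA)
        assert ranking.summary.sum() == pytest.approx(100.0)


class TestRiparian:
    def test_crossed_hexagon_flagged(self):
        cells = build_hexgrid(box(0, 0, 2000, 2000))
        river = LineString([(0, 1000), (2000, 1000)])
        rip = riparian_subset(cells, [river])
        assert rip
        assert all(c.geometry.intersects(river) for c in rip)

    def test_distant_hexagon_not_flagged(self):
        cells = build_hexgrid(box(0, 0, 2000, 2000))
        river = LineString([(0, 50_000), (2000, 50_000)])
        assert riparian_subset(cells, [river]) == []

    def test_count_matches_allpairs_oracle(self):
        cells = build_hexgrid(box(0, 0, 3000, 3000))
        rivers = [LineString([(0, 0), (3000, 3000)]), LineString([(0, 2500), (3000, 2400)])]
        rip = riparian_subset(cells, rivers)
        oracle = sum(
            1 for c in cells if any(c.geometry.intersects(r) for r in rivers)
        )
        assert len(rip) == oracle


class TestConeforExport:
    def test_file_shapes_and_roundtrip(self, tmp_path):
        patches = [
            HabitatPatch(0, box(0, 0, 10, 10), 100.0, 1.25),
            HabitatPatch(1, box(50, 0, 60, 10), 100.0, 2.5),
            HabitatPatch(2, box(0, 50, 10, 60), 100.0, 0.75),
        ]
        node_path, dist_path = export_conefor(patches, [], tmp_path)
        nodes, dists = read_conefor(node_path, dist_path)
        assert len(nodes) == 3
        assert len(dists) == 3  # C(3,2)
        assert nodes[1] == 2.5  # exact round trip

    def test_external_recompute_matches_compute_iic(self, tmp_path):
        rng = np.random.default_rng(11)
        patches = random_patchset(rng, n_max=8)
        node_path, dist_path = export_conefor(patches, [], tmp_path)
        nodes, dists = read_conefor(node_path, dist_path)
        for d in (500.0, 1500.0):
            external = iic_from_conefor(nodes, dists, d, A_L=25_000_000.0)
            assert abs(external - compute_iic(patches, d, 25_000_000.0)) < 1e-9
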