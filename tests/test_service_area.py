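"""Isochrone reach, coverage polygons and the SAR/SPR ratios."""

import math

import networkx as nx
import numpy as np
import pytest
import shapely
from shapely.geometry import Point, box

from medaccess.network import NetworkParams, build_multimodal_graph, build_walk_graph
from medaccess.raster import Raster
from medaccess.service_area import (
    AccessConfig,
    coverage_polygon,
    facility_sources,
    multi_source_reach,
    run_accessibility,
    sar,
    spr,
)

PARAMS = NetworkParams()


def random_toy_graph(rng, n_nodes):
    """Connected random walk-type graph with symmetric positive costs and node coords."""
    g = nx.DiGraph()
    coords = rng.uniform(0, 1000, size=(n_nodes, 2))
    for i, (x, y) in enumerate(coords):
        g.add_node(i, x=float(x), y=float(y), kind="walk")
    for i in range(1, n_nodes):  # spanning tree keeps it connected
        j = int(rng.integers(0, i))
        _add_pair(g, i, j, float(rng.uniform(10, 120)))
    for _ in range(n_nodes):
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j and not g.has_edge(int(i), int(j)):
            _add_pair(g, int(i), int(j), float(rng.uniform(10, 120)))
    return g


def _add_pair(g, u, v, cost):
    g.add_edge(u, v, type="walk", cost_s=cost, length_m=cost * 1.2)
    g.add_edge(v, u, type="walk", cost_s=cost, length_m=cost * 1.2)


def brute_force_reached(g, sources, budget):
    """Exhaustive simple-path enumeration: independent of the Dijkstra implementation."""
    best = {}
    for src, init in sources:
        if init <= budget:
            best[src] = min(best.get(src, math.inf), init)
        for target in g.nodes:
            if target == src:
                continue
            for path in nx.all_simple_paths(g, src, target):
                c = init + sum(g[a][b]["cost_s"] for a, b in zip(path, path[1:]))
                if c < best.get(target, math.inf):
                    best[target] = c
    return {n: c for n, c in best.items() if c <= budget}


class TestMultiSourceReach:
    def test_matches_brute_force_on_random_graphs(self, rng):
        for k in range(50):
            g = random_toy_graph(rng, int(rng.integers(4, 13)))
            nodes = list(g.nodes)
            n_src = int(rng.integers(1, 3))
            sources = [(nodes[int(rng.integers(len(nodes)))], float(rng.uniform(0, 30))) for _ in range(n_src)]
            budget = float(rng.uniform(50, 250))
            reach = multi_source_reach(g, sources, budget)
            oracle = brute_force_reached(g, sources, budget)
            assert set(reach.node_costs) == set(oracle), f"graph {k}"
            for n, c in oracle.items():
                assert reach.node_costs[n] == pytest.approx(c), f"graph {k} node {n}"

    def test_tiny_budget_reaches_only_sources(self):
        g = build_walk_graph([((0.0, 0.0), (120.0, 0.0), 120.0)], PARAMS)
        src = [(("w", (0.0, 0.0)), 0.0)]
        reach = multi_source_reach(g, src, 1e-3)
        assert set(reach.node_costs) == {("w", (0.0, 0.0))}
        (fracs,) = reach.covered.values()
        assert max(fracs) < 1e-4  # only an epsilon sliver of the incident edge

    def test_saturating_budget_covers_every_edge(self, line_graph):
        g, _ = line_graph
        total = sum(d["cost_s"] for _, _, d in g.edges(data=True))
        reach = multi_source_reach(g, [(("w", (0.0, 0.0)), 0.0)], total)
        walk_access = {frozenset(k) for k, f in reach.covered.items() if f == (1.0, 1.0)}
        n_pairs = g.number_of_edges() // 2
        assert len(reach.covered) == n_pairs
        assert len(walk_access) == n_pairs

    def test_nestedness_of_budgets(self, rng):
        g = random_toy_graph(rng, 10)
        sources = [(0, 0.0)]
        prev = set()
        for budget in (40.0, 90.0, 200.0):
            reached = set(multi_source_reach(g, sources, budget).node_costs)
            assert prev <= reached
            prev = reached

    def test_empty_sources_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            multi_source_reach(random_toy_graph(rng, 5), [], 100.0)

    def test_transit_never_reduces_reachability(self, small_city):
        params = NetworkParams()
        walk_only = build_walk_graph(small_city.walk_edges, params)
        full = build_multimodal_graph(small_city.walk_edges, small_city.stations, small_city.transit_lines, params)
        sources, _ = facility_sources(small_city.facilities["hospital"], walk_only, params)
        budget = 900.0
        r_walk = multi_source_reach(walk_only, sources, budget)
        r_full = multi_source_reach(full, sources, budget)
        walk_nodes = {n for n in r_walk.node_costs}
        assert walk_nodes <= set(r_full.node_costs)
        for n in walk_nodes:
            assert r_full.node_costs[n] <= r_walk.node_costs[n] + 1e-9


class TestCoveragePolygon:
    def test_stadium_area_of_single_segment(self):
        g = build_walk_graph([((0.0, 0.0), (500.0, 0.0), 500.0)], PARAMS)
        reach = multi_source_reach(g, [(("w", (0.0, 0.0)), 0.0)], 1e9)
        w = 50.0
        poly = coverage_polygon(reach, g, w)
        assert poly.area == pytest.approx(2 * w * 500.0 + math.pi * w**2, rel=0.01)

    def test_empty_reach_gives_empty_polygon(self):
        from medaccess.service_area import Reach

        g = build_walk_graph([((0.0, 0.0), (10.0, 0.0), 10.0)], PARAMS)
        poly = coverage_polygon(Reach(budget=1.0, node_costs={}, covered={}), g, 50.0)
        assert poly.is_empty

    def test_disjoint_components_sum_areas(self):
        """Geometry-engine oracle: two far-apart covered segments make a 2-part multipolygon."""
        edges = [((0.0, 0.0), (200.0, 0.0), 200.0), ((10000.0, 0.0), (10200.0, 0.0), 200.0)]
        g = build_walk_graph(edges, PARAMS)
        sources = [(("w", (0.0, 0.0)), 0.0), (("w", (10000.0, 0.0)), 0.0)]
        reach = multi_source_reach(g, sources, 500.0)
        poly = coverage_polygon(reach, g, 30.0)
        assert poly.geom_type == "MultiPolygon" and len(poly.geoms) == 2
        assert poly.area == pytest.approx(sum(p.area for p in poly.geoms))


class TestRatios:
    DISTRICT = box(0, 0, 1000, 1000)

    def test_sar_containment_and_disjoint(self):
        assert sar(box(-100, -100, 2000, 2000), self.DISTRICT) == pytest.approx(1.0)
        assert sar(box(5000, 5000, 6000, 6000), self.DISTRICT) == 0.0

    def test_sar_half_plane_clip(self):
        assert sar(box(0, 0, 500, 1000), self.DISTRICT) == pytest.approx(0.5)

    def test_sar_degenerate_district_rejected(self):
        with pytest.raises(ValueError):
            sar(box(0, 0, 1, 1), Point(0, 0).buffer(0))

    def _uniform_raster(self):
        return Raster(origin=(0.0, 0.0), cell_size=100.0, values=np.ones((10, 10)))

    def test_spr_uniform_half_coverage(self):
        assert spr(box(0, 0, 500, 1000), self._uniform_raster(), self.DISTRICT) == pytest.approx(0.5)

    def test_spr_no_populated_cell_covered(self):
        assert spr(box(2000, 2000, 3000, 3000), self._uniform_raster(), self.DISTRICT) == 0.0

    def test_spr_empty_district_is_nan_not_zero(self):
        empty = box(50000, 50000, 51000, 51000)
        assert math.isnan(spr(box(0, 0, 10, 10), self._uniform_raster(), empty))

    def test_spr_matches_cell_by_cell_scan(self, rng):
        """Brute-force containment oracle over every cell center."""
        raster = Raster(origin=(0.0, 0.0), cell_size=100.0, values=rng.uniform(0, 50, size=(10, 10)))
        poly = Point(420, 380).buffer(333)
        expected_sp = expected_tp = 0.0
        for j in range(10):
            for i in range(10):
                c = Point(100 * i + 50, 100 * j + 50)
                if self.DISTRICT.contains(c):
                    expected_tp += raster.values[j, i]
                    if poly.contains(c):
                        expected_sp += raster.values[j, i]
        assert spr(poly, raster, self.DISTRICT) == pytest.approx(expected_sp / expected_tp)


class TestRunAccessibility:
    def test_monotone_in_threshold_and_bounded(self, small_city):
        g = build_multimodal_graph(small_city.walk_edges, small_city.stations, small_city.transit_lines, PARAMS)
        result = run_accessibility(small_city, g, AccessConfig(buffer_width=200.0), PARAMS)
        df = result.records
        assert ((df["SAR"] >= 0) & (df["SAR"] <= 1)).all()
        assert ((df["SPR"] >= 0) & (df["SPR"] <= 1)).all()
        for _, sub in df.sort_values("threshold_min").groupby(["district", "facility_class"]):
            for col in ("SAR", "SPR"):
                s = sub[col].to_numpy()
                assert (s[1:] >= s[:-1] - 1e-9).all()

    def test_isochrone_polygons_nest(self, small_city):
        g = build_multimodal_graph(small_city.walk_edges, small_city.stations, small_city.transit_lines, PARAMS)
        result = run_accessibility(small_city, g, AccessConfig(buffer_width=200.0), PARAMS)
        by_class = {}
        for iso in result.isochrones:
            by_class.setdefault(iso.facility_class, []).append(iso)
        for isos in by_class.values():
            isos.sort(key=lambda i: i.threshold_min)
            for a, b in zip(isos, isos[1:]):
                assert b.polygon.buffer(1e-6).contains(a.polygon)

    def test_saturation_sar_reaches_one(self):
        """One central facility, generous budget and buffer: the district is fully served."""
        from medaccess.point_pattern import PointPattern
        from medaccess.synthetic_city import CityParams, FacilitySpec, SyntheticCity, TransitSpec
        from medaccess.synthetic_city import generate_city

        params = CityParams(
            seed=2, grid_nx=4, grid_ny=4, block_spacing=200.0, n_districts=1,
            raster_cell=100.0, pop_centers=((300.0, 300.0, 1000.0, 300.0),),
            facility_specs={"h": FacilitySpec(n=2, process="uniform")},
            transit_specs={},
        )
        city = generate_city(params)
        g = build_multimodal_graph(city.walk_edges, [], [], PARAMS)
        result = run_accessibility(city, g, AccessConfig(thresholds=(60.0,), buffer_width=400.0), PARAMS)
        assert result.records["SAR"].iloc[0] == pytest.approx(1.0)
        assert result.records["SPR"].iloc[0] == pytest.approx(1.0)

    def test_conservation_of_served_population(self, small_city):
        g = build_multimodal_graph(small_city.walk_edges, small_city.stations, small_city.transit_lines, PARAMS)
        result = run_accessibility(small_city, g, AccessConfig(buffer_width=200.0), PARAMS)
        total = small_city.population.total()
        per_slice = result.records.groupby(["facility_class", "threshold_min"])["sp"].sum()
        assert (per_slice <= total * (1 + 1e-9)).all()

    def test_clustered_class_advantages_home_district(self, small_city):
        """Facilities cluster in few districts; at 15 min those districts out-serve the remotest one."""
        g = build_multimodal_graph(small_city.walk_edges, small_city.stations, small_city.transit_lines, PARAMS)
        result = run_accessibility(small_city, g, AccessConfig(buffer_width=200.0), PARAMS)
        df = result.records
        at15 = df[(df["facility_class"] == "clinic") & (df["threshold_min"] == 15.0)]
        assert at15["SPR"].max() > at15["SPR"].min()
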