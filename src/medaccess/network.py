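"""Multimodal travel-time graph: walking, bus and rail with station transfers.

The network model has three layers joined at stations:

* **walk** edges — road centerlines traversed at walking speed in both
  directions;
* **access** edges — each (station, line) pair gets a *platform* node
  connected to the nearest walk node, crossed at walking speed over the
  snap distance, so boarding always pays the real walk to the stop;
* **ride** edges — consecutive stations of a line, traversed at the
  mode's speed plus a fixed dwell (stop) delay per segment.

Every edge carries ``cost_s`` (seconds) and ``length_m``; all costs are
symmetric, stored as directed edge pairs in a :class:`networkx.DiGraph`.
Transfers between lines at a shared stop route through the common walk
anchor node, paying both access walks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "NetworkParams",
    "Station",
    "TransitLine",
    "SnapError",
    "build_walk_graph",
    "attach_stations",
    "add_ride_edges",
    "build_multimodal_graph",
    "validate_graph",
    "walk_node_index",
]

KMH = 1 / 3.6  # km/h → m/s


@dataclass(frozen=True)
class NetworkParams:
    """Travel speeds (m/s), dwell delay (s) and station snap tolerance (m).

    Defaults: walking 1.2 m/s, buses 40 km/h, rail 70 km/h (urban design
    speeds adjusted for hilly terrain), 30 s stop time, 500 m snap tolerance.
    """

    v_walk: float = 1.2
    v_bus: float = 40.0 * KMH
    v_rail: float = 70.0 * KMH
    dwell: float = 30.0
    snap_tolerance: float = 500.0

    def __post_init__(self) -> None:
        for name in ("v_walk", "v_bus", "v_rail"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dwell < 0:
            raise ValueError("dwell must be non-negative")

    def mode_speed(self, mode: str) -> float:
        try:
            return {"bus": self.v_bus, "rail": self.v_rail, "walk": self.v_walk}[mode]
        except KeyError:
            raise ValueError(f"unknown mode {mode!r}") from None


@dataclass
class Station:
    """A transit stop; the transfer point between walking and riding."""

    id: str
    location: tuple[float, float]
    mode: str  # "bus" | "rail"
    line_ids: list[str] = field(default_factory=list)
    anchor_node: object | None = None
    snap_distance: float = math.nan


@dataclass
class TransitLine:
    """An ordered sequence of stations served by one bus or rail line."""

    id: str
    mode: str
    station_ids: list[str]
    alignment: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("bus", "rail"):
            raise ValueError(f"line {self.id}: mode must be bus or rail, got {self.mode!r}")


class SnapError(ValueError):
    """A station or facility lies farther than snap_tolerance from the walk network."""


def _quantize(p, grid: float = 0.01):
    return (round(p[0] / grid) * grid, round(p[1] / grid) * grid)


def build_walk_graph(walk_edges, params: NetworkParams) -> nx.DiGraph:
    """Build the walking layer from road segments.

    ``walk_edges`` is an iterable of ``(p1, p2)`` or ``(p1, p2, length)``
    tuples with endpoints in meters; endpoints within 0.01 m are merged
    into one node. Each segment becomes a directed edge pair with
    ``cost_s = length / v_walk``. Zero/non-positive length segments are
    dropped (counted in the graph's ``rejected_edges`` attribute).
    """
    g = nx.DiGraph()
    rejected = []
    for k, e in enumerate(walk_edges):
        if len(e) == 3:
            p1, p2, length = e
        else:
            p1, p2 = e
            length = math.dist(p1, p2)
        if length <= 0:
            rejected.append(k)
            continue
        u = ("w", _quantize(p1))
        v = ("w", _quantize(p2))
        for node, p in ((u, p1), (v, p2)):
            if node not in g:
                g.add_node(node, x=float(p[0]), y=float(p[1]), kind="walk")
        cost = length / params.v_walk
        g.add_edge(u, v, type="walk", length_m=float(length), cost_s=cost)
        g.add_edge(v, u, type="walk", length_m=float(length), cost_s=cost)
    g.graph["rejected_edges"] = rejected
    g.graph["params"] = params
    return g


def walk_node_index(graph: nx.DiGraph) -> tuple[list, cKDTree]:
    """KD-tree over walk-node coordinates for nearest-node snapping."""
    nodes = [n for n, d in graph.nodes(data=True) if d.get("kind") == "walk"]
    coords = np.array([[graph.nodes[n]["x"], graph.nodes[n]["y"]] for n in nodes])
    return nodes, cKDTree(coords)


def attach_stations(graph: nx.DiGraph, stations: list[Station], params: NetworkParams) -> nx.DiGraph:
    """Create platform nodes and access edges for each (station, line).

    Mutates and returns ``graph``. Each platform is tied to the nearest
    walk node by a bidirectional access edge costing the snap distance
    at walking speed. Stations beyond ``snap_tolerance`` raise
    :class:`SnapError` listing the offenders.
    """
    nodes, tree = walk_node_index(graph)
    too_far = []
    for st in stations:
        dist, idx = tree.query(st.location)
        if dist > params.snap_tolerance:
            too_far.append(st.id)
            continue
        st.anchor_node = nodes[int(idx)]
        st.snap_distance = float(dist)
        cost = st.snap_distance / params.v_walk
        for line_id in st.line_ids or [None]:
            pf = ("p", line_id, st.id)
            graph.add_node(
                pf,
                x=st.location[0],
                y=st.location[1],
                kind="platform",
                station=st.id,
                line=line_id,
                mode=st.mode,
            )
            graph.add_edge(pf, st.anchor_node, type="access", length_m=st.snap_distance, cost_s=cost)
            graph.add_edge(st.anchor_node, pf, type="access", length_m=st.snap_distance, cost_s=cost)
    if too_far:
        raise SnapError(f"stations beyond snap tolerance {params.snap_tolerance} m: {too_far}")
    return graph


def _alignment_distances(line: TransitLine, locs: list[tuple[float, float]]) -> list[float]:
    """Inter-station distances along the alignment polyline (projected arc length)."""
    from shapely.geometry import LineString, Point

    ls = LineString(line.alignment)
    s = [ls.project(Point(p)) for p in locs]
    if any(b < a for a, b in zip(s, s[1:])):
        raise ValueError(f"line {line.id}: station order does not follow the alignment")
    return [b - a for a, b in zip(s, s[1:])]


def add_ride_edges(graph: nx.DiGraph, lines: list[TransitLine], stations: list[Station], params: NetworkParams) -> nx.DiGraph:
    """Add in-vehicle edges between consecutive platforms of each line.

    Cost per segment = inter-station distance / mode speed + dwell, so a
    k-segment ride accumulates k dwell penalties and boarding itself is
    free of dwell. Distance is measured along the alignment polyline
    when the line has one, else Euclidean. Lines with < 2 stations are
    rejected.
    """
    by_id = {s.id: s for s in stations}
    for line in lines:
        if len(line.station_ids) < 2:
            raise ValueError(f"line {line.id}: needs at least 2 stations")
        locs = [by_id[sid].location for sid in line.station_ids]
        if line.alignment is not None:
            dists = _alignment_distances(line, locs)
        else:
            dists = [math.dist(a, b) for a, b in zip(locs, locs[1:])]
        speed = params.mode_speed(line.mode)
        for (a, b), d in zip(zip(line.station_ids, line.station_ids[1:]), dists):
            if d <= 0:
                raise ValueError(f"line {line.id}: consecutive stations {a}, {b} coincide")
            cost = d / speed + params.dwell
            pa, pb = ("p", line.id, a), ("p", line.id, b)
            graph.add_edge(pa, pb, type="ride", length_m=float(d), cost_s=cost, mode=line.mode)
            graph.add_edge(pb, pa, type="ride", length_m=float(d), cost_s=cost, mode=line.mode)
    return graph


def build_multimodal_graph(walk_edges, stations: list[Station], lines: list[TransitLine], params: NetworkParams | None = None) -> nx.DiGraph:
    """Convenience: walk layer + station access + ride edges in one call."""
    params = params or NetworkParams()
    g = build_walk_graph(walk_edges, params)
    attach_stations(g, stations, params)
    add_ride_edges(g, lines, stations, params)
    return g


def validate_graph(graph: nx.DiGraph) -> dict:
    """Diagnostic report: component/orphan/negative-cost counts by type."""
    walk_nodes = [n for n, d in graph.nodes(data=True) if d.get("kind") == "walk"]
    platforms = [n for n, d in graph.nodes(data=True) if d.get("kind") == "platform"]
    walk_sub = graph.subgraph(walk_nodes).to_undirected()
    n_components = nx.number_connected_components(walk_sub) if walk_nodes else 0
    orphans = [n for n in platforms if not any(graph[n][v]["type"] == "access" for v in graph[n])]
    edge_counts: dict[str, int] = {}
    negative = []
    for u, v, d in graph.edges(data=True):
        edge_counts[d["type"]] = edge_counts.get(d["type"], 0) + 1
        if d["cost_s"] < 0:
            negative.append((u, v))
    return {
        "walk_nodes": len(walk_nodes),
        "platform_nodes": len(platforms),
        "walk_components": n_components,
        "orphan_platforms": orphans,
        "negative_cost_edges": negative,
        "edge_counts": edge_counts,
    }
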