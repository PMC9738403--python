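"""Isochrone service areas and the SAR/SPR accessibility statistics.

From every facility of a class, travel-time reach over the multimodal
graph is expanded simultaneously (multi-source Dijkstra) up to each time
threshold (default 15/30/60 min). The reached walking/access edge
portions are buffered into a service-area polygon, and for every
district two ratios are reported:

* ``SAR = sa / ta`` — service area inside the district over district area;
* ``SPR = sp / tp`` — population inside the service area over district
  population, with raster cells assigned by their center point.

Ride (in-vehicle) edges carry reach between stations but contribute no
coverage geometry: one cannot exit a vehicle mid-segment, so only the
street network reached on foot is "served".
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

from .network import NetworkParams, walk_node_index
from .point_pattern import PointPattern
from .raster import Raster

__all__ = [
    "AccessConfig",
    "Reach",
    "Isochrone",
    "AccessResult",
    "facility_sources",
    "multi_source_reach",
    "coverage_polygon",
    "sar",
    "spr",
    "run_accessibility",
    "access_averages",
]


@dataclass(frozen=True)
class AccessConfig:
    """Service-area thresholds (minutes), polygon buffer width (m), cell rule."""

    thresholds: tuple = (15.0, 30.0, 60.0)
    buffer_width: float = 50.0
    cell_rule: str = "center"

    def __post_init__(self) -> None:
        th = tuple(float(t) for t in self.thresholds)
        if any(t <= 0 for t in th) or any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be positive and strictly increasing")
        if self.buffer_width <= 0:
            raise ValueError("buffer_width must be positive")
        if self.cell_rule != "center":
            raise ValueError("only the center-in-polygon cell rule is implemented")
        object.__setattr__(self, "thresholds", th)


@dataclass
class Reach:
    """Result of a multi-source expansion at one time budget.

    ``node_costs`` maps reached node → min travel time (s);
    ``covered`` maps a canonical (u, v) edge pair → (fraction covered
    from u, fraction covered from v), each in [0, 1].
    """

    budget: float
    node_costs: dict
    covered: dict


@dataclass
class Isochrone:
    """Reached subnetwork and coverage polygon for one class and threshold."""

    facility_class: str
    threshold_min: float
    reach: Reach
    polygon: shapely.Geometry
    source_count: int


@dataclass
class AccessResult:
    """AccessRecord table plus the per-class / per-district average pivots."""

    records: pd.DataFrame
    class_averages: pd.DataFrame
    district_averages: pd.DataFrame
    isochrones: list = field(default_factory=list)
    report: dict = field(default_factory=dict)


def facility_sources(
    facilities: PointPattern, graph, params: NetworkParams
) -> tuple[list, int]:
    """Snap each facility to its nearest walk node.

    Returns ``(sources, n_unsnapped)`` where sources are
    ``(node, initial_cost_s)`` pairs, the initial cost being the snap
    distance at walking speed. Facilities beyond ``snap_tolerance`` are
    excluded with a warning and counted, not fatal.
    """
    nodes, tree = walk_node_index(graph)
    dists, idxs = tree.query(facilities.points)
    sources, unsnapped = [], 0
    for d, i in zip(np.atleast_1d(dists), np.atleast_1d(idxs)):
        if d > params.snap_tolerance:
            unsnapped += 1
            continue
        sources.append((nodes[int(i)], float(d) / params.v_walk))
    if unsnapped:
        warnings.warn(
            f"{unsnapped} facilities beyond snap tolerance {params.snap_tolerance} m excluded",
            stacklevel=2,
        )
    return sources, unsnapped


def multi_source_reach(graph, sources: list, budget: float) -> Reach:
    """Expand travel time from all sources simultaneously up to ``budget`` s.

    A heap-based Dijkstra seeded with each source's initial cost. A node
    is reached if its min cost ≤ budget. A walk/access edge is covered
    fully when it is traversable within budget from either end, else
    partially up to the remaining time converted at the edge's own
    speed; ride edges are all-or-nothing (no mid-segment exit).
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    if not sources:
        raise ValueError("source list is empty")
    dist: dict = {}
    heap = []
    tick = 0  # deterministic tie-break: insertion order
    for node, init in sources:
        if init <= budget and init < dist.get(node, math.inf):
            dist[node] = init
            heapq.heappush(heap, (init, tick, node))
            tick += 1
    while heap:
        d, _, u = heapq.heappop(heap)
        if d > dist.get(u, math.inf):
            continue
        for v in graph.successors(u):
            nd = d + graph[u][v]["cost_s"]
            if nd <= budget and nd < dist.get(v, math.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, tick, v))
                tick += 1
    covered: dict = {}
    for u, v, data in graph.edges(data=True):
        key = (u, v) if _node_key(u) <= _node_key(v) else (v, u)
        if key in covered:
            continue
        c = data["cost_s"]
        du, dv = dist.get(key[0], math.inf), dist.get(key[1], math.inf)
        if data["type"] == "ride":
            full = du + c <= budget or dv + c <= budget
            if full:
                covered[key] = (1.0, 1.0)
            continue
        if du + c <= budget or dv + c <= budget:
            covered[key] = (1.0, 1.0)
            continue
        fu = max(0.0, min(1.0, (budget - du) / c)) if du < math.inf else 0.0
        fv = max(0.0, min(1.0, (budget - dv) / c)) if dv < math.inf else 0.0
        if fu > 0 or fv > 0:
            covered[key] = (fu, fv)
    return Reach(budget=float(budget), node_costs=dist, covered=covered)


def _node_key(n) -> str:
    return repr(n)


def _node_xy(graph, n) -> tuple[float, float]:
    d = graph.nodes[n]
    return (d["x"], d["y"])


def coverage_polygon(reach: Reach, graph, buffer_width: float):
    """Union of round-capped buffers over the covered walk/access portions.

    Ride edges are excluded from the geometry (connectivity only).
    Returns an empty polygon for an empty reach.
    """
    if buffer_width <= 0:
        raise ValueError("buffer_width must be positive")
    parts = []
    for (u, v), (fu, fv) in reach.covered.items():
        if graph.has_edge(u, v) and graph[u][v]["type"] == "ride":
            continue
        pu, pv = _node_xy(graph, u), _node_xy(graph, v)
        if fu >= 1.0 or fv >= 1.0:
            parts.append(LineString([pu, pv]))
            continue
        if fu > 0:
            q = (pu[0] + fu * (pv[0] - pu[0]), pu[1] + fu * (pv[1] - pu[1]))
            parts.append(LineString([pu, q]))
        if fv > 0:
            q = (pv[0] + fv * (pu[0] - pv[0]), pv[1] + fv * (pu[1] - pv[1]))
            parts.append(LineString([pv, q]))
    for n in reach.node_costs:
        parts.append(Point(_node_xy(graph, n)))
    if not parts:
        return shapely.Polygon()
    return unary_union([g.buffer(buffer_width) for g in parts])


def sar(polygon, district) -> float:
    """Service-area ratio: area(polygon ∩ district) / area(district)."""
    if district.area <= 0:
        raise ValueError("district has zero area")
    return polygon.intersection(district).area / district.area


def spr(polygon, raster: Raster, district) -> float:
    """Service-population ratio: population of cells (by center) inside polygon ∩ district over district population.

    Returns NaN when the district contains no populated cell.
    """
    cx, cy = raster.cell_centers()
    X, Y = np.meshgrid(cx, cy)
    in_district = shapely.contains_xy(district, X.ravel(), Y.ravel()).reshape(X.shape)
    tp = float(raster.values[in_district].sum())
    if tp <= 0:
        return float("nan")
    in_poly = shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(X.shape)
    sp = float(raster.values[in_district & in_poly].sum())
    return sp / tp


def run_accessibility(city, graph, config: AccessConfig | None = None, params: NetworkParams | None = None) -> AccessResult:
    """Full accessibility table for a city over every class × threshold × district.

    One isochrone per (facility class, threshold) from the union of that
    class's snapped sources. Classes with no snappable facility yield
    zero rows flagged ``empty``.
    """
    config = config or AccessConfig()
    params = params or graph.graph.get("params") or NetworkParams()
    rows = []
    isochrones = []
    report = {"unsnapped": {}, "buffer_width": config.buffer_width, "thresholds_min": list(config.thresholds)}
    cx, cy = city.population.cell_centers()
    X, Y = np.meshgrid(cx, cy)
    district_masks = {
        name: shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
        for name, poly in city.districts.items()
    }
    for cls in sorted(city.facilities):
        pattern = city.facilities[cls]
        sources, unsnapped = facility_sources(pattern, graph, params)
        report["unsnapped"][cls] = unsnapped
        for thr in config.thresholds:
            if sources:
                reach = multi_source_reach(graph, sources, thr * 60.0)
                poly = coverage_polygon(reach, graph, config.buffer_width)
            else:
                reach = Reach(budget=thr * 60.0, node_costs={}, covered={})
                poly = shapely.Polygon()
            isochrones.append(
                Isochrone(facility_class=cls, threshold_min=thr, reach=reach, polygon=poly, source_count=len(sources))
            )
            in_poly = (
                shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
                if not poly.is_empty
                else np.zeros(X.shape, dtype=bool)
            )
            for name, district in city.districts.items():
                mask = district_masks[name]
                ta = district.area
                sa = poly.intersection(district).area if not poly.is_empty else 0.0
                tp = float(city.population.values[mask].sum())
                sp = float(city.population.values[mask & in_poly].sum())
                rows.append(
                    {
                        "district": name,
                        "facility_class": cls,
                        "threshold_min": thr,
                        "sa_m2": sa,
                        "ta_m2": ta,
                        "sp": sp,
                        "tp": tp,
                        # clamp guards float rounding in the polygon intersection
                        "SAR": min(sa / ta, 1.0),
                        "SPR": min(sp / tp, 1.0) if tp > 0 else float("nan"),
                        "empty": not sources,
                    }
                )
    records = pd.DataFrame(rows)
    class_avg, district_avg = access_averages(records)
    return AccessResult(
        records=records,
        class_averages=class_avg,
        district_averages=district_avg,
        isochrones=isochrones,
        report=report,
    )


def access_averages(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arithmetic-mean pivots: per class (across districts) and per district (across classes)."""
    class_avg = (
        records.groupby(["facility_class", "threshold_min"])[["SAR", "SPR"]].mean().reset_index()
    )
    district_avg = (
        records.groupby(["district", "threshold_min"])[["SAR", "SPR"]].mean().reset_index()
    )
    return class_avg, district_avg
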