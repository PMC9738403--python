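"""GeoJSON / CSV readers and writers for pipeline artifacts.

All vector data is plain GeoJSON (planar meter coordinates, no CRS
member); rasters are ESRI ASCII grids; tables are CSV with a single
``#``-prefixed provenance comment line carrying the run's config hash
and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .network import Station, TransitLine
from .point_pattern import PointPattern

__all__ = [
    "write_points_geojson",
    "read_facilities",
    "write_lines_geojson",
    "read_walk_edges_geojson",
    "write_polygons_geojson",
    "read_polygons_geojson",
    "write_stations_geojson",
    "read_stations_geojson",
    "write_transit_lines_csv",
    "read_transit_lines_csv",
    "write_graph_csv",
    "write_isochrones_geojson",
    "write_table",
    "read_table",
]


def _dump(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _feature(geom, props: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def _collection(features: list) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_points_geojson(patterns: dict, path, prop: str = "class") -> None:
    """Write {label -> PointPattern} as a GeoJSON point collection."""
    from shapely.geometry import Point

    feats = []
    for label in sorted(patterns):
        for x, y in patterns[label].points:
            feats.append(_feature(Point(x, y), {prop: label}))
    _dump(_collection(feats), path)


def read_facilities(path, prop: str = "class") -> dict:
    """Read labeled points from GeoJSON or CSV (columns x, y, class) into {label -> PointPattern}."""
    path = Path(path)
    groups: dict[str, list] = {}
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, comment="#")
        for label, sub in df.groupby(prop):
            groups[str(label)] = sub[["x", "y"]].to_numpy(dtype=float).tolist()
    else:
        gj = json.loads(path.read_text())
        for feat in gj["features"]:
            label = str(feat["properties"].get(prop, ""))
            x, y = feat["geometry"]["coordinates"][:2]
            groups.setdefault(label, []).append((x, y))
    return {label: PointPattern(points=np.array(pts), label=label) for label, pts in sorted(groups.items())}


def write_lines_geojson(walk_edges, path) -> None:
    """Write walk segments as LineStrings with a length_m property."""
    from shapely.geometry import LineString

    feats = []
    for e in walk_edges:
        p1, p2, length = (e if len(e) == 3 else (*e, None))
        ls = LineString([p1, p2])
        feats.append(_feature(ls, {"length_m": float(length) if length is not None else ls.length}))
    _dump(_collection(feats), path)


def read_walk_edges_geojson(path) -> list:
    gj = json.loads(Path(path).read_text())
    edges = []
    for feat in gj["features"]:
        coords = feat["geometry"]["coordinates"]
        length = feat["properties"].get("length_m")
        for p1, p2 in zip(coords, coords[1:]):
            seg_len = float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))
            # a stated length applies to single-segment features only
            use = float(length) if (length is not None and len(coords) == 2) else seg_len
            edges.append((tuple(p1), tuple(p2), use))
    return edges


def write_polygons_geojson(polygons: dict, path, prop: str = "name") -> None:
    feats = [_feature(polygons[name], {prop: name}) for name in sorted(polygons)]
    _dump(_collection(feats), path)


def read_polygons_geojson(path, prop: str = "name") -> dict:
    gj = json.loads(Path(path).read_text())
    return {str(f["properties"][prop]): shape(f["geometry"]) for f in gj["features"]}


def write_stations_geojson(stations: list, path) -> None:
    from shapely.geometry import Point

    feats = [
        _feature(
            Point(*st.location),
            {"id": st.id, "mode": st.mode, "line_ids": list(st.line_ids)},
        )
        for st in stations
    ]
    _dump(_collection(feats), path)


def read_stations_geojson(path) -> list:
    gj = json.loads(Path(path).read_text())
    stations = []
    for f in gj["features"]:
        p = f["properties"]
        x, y = f["geometry"]["coordinates"][:2]
        stations.append(Station(id=str(p["id"]), location=(x, y), mode=p["mode"], line_ids=list(p["line_ids"])))
    return stations


def write_transit_lines_csv(lines: list, path) -> None:
    rows = [
        {"line_id": ln.id, "mode": ln.mode, "station_ids": " ".join(ln.station_ids)}
        for ln in lines
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_transit_lines_csv(path) -> list:
    df = pd.read_csv(path, comment="#")
    return [
        TransitLine(id=str(r.line_id), mode=str(r.mode), station_ids=str(r.station_ids).split())
        for r in df.itertuples()
    ]


def write_graph_csv(graph, nodes_path, edges_path) -> None:
    """Dump the multimodal graph as node and edge CSVs for inspection/reload."""
    nodes = [
        {"id": repr(n), "kind": d.get("kind", ""), "x": d["x"], "y": d["y"]}
        for n, d in sorted(graph.nodes(data=True), key=lambda nd: repr(nd[0]))
    ]
    pd.DataFrame(nodes).to_csv(nodes_path, index=False)
    edges = [
        {"from": repr(u), "to": repr(v), "type": d["type"], "length_m": d["length_m"], "cost_s": d["cost_s"]}
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (repr(e[0]), repr(e[1])))
    ]
    pd.DataFrame(edges).to_csv(edges_path, index=False)


def write_isochrones_geojson(isochrones: list, path) -> None:
    feats = [
        _feature(
            iso.polygon,
            {
                "facility_class": iso.facility_class,
                "threshold_min": iso.threshold_min,
                "source_count": iso.source_count,
            },
        )
        for iso in isochrones
        if not iso.polygon.is_empty
    ]
    _dump(_collection(feats), path)


def write_table(df: pd.DataFrame, path, config_hash: str = "", seed=None) -> None:
    """CSV with one provenance comment line (config hash + seed) before the header."""
    with open(path, "w") as fh:
        fh.write(f"# medaccess config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
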