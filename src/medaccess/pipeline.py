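"""Run configuration and end-to-end pipeline orchestration.

A single YAML/JSON config drives both synthetic and file-input modes.
The pipeline stages are, in order: build or load the city → point-pattern
tables (nearest-neighbor, mean center + deviational ellipse, kernel
density grids) → multimodal graph → isochrones → accessibility (SAR/SPR)
tables. Every table written carries the config hash and seed so any
number can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .network import NetworkParams, build_multimodal_graph, validate_graph
from .point_pattern import (
    PointPattern,
    kernel_density,
    mean_center,
    nn_analysis,
    standard_deviational_ellipse,
)
from .raster import Raster, read_ascii_grid, write_ascii_grid
from .service_area import AccessConfig, access_averages, run_accessibility
from .synthetic_city import CityParams, FacilitySpec, SyntheticCity, TransitSpec, generate_city

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "load_config",
    "run_pipeline",
    "report_tables",
    "format_percent",
    "toy_config",
    "demo_config",
]

log = logging.getLogger("medaccess")

KMH = 1 / 3.6

_TOP_KEYS = {"seed", "city", "inputs", "network", "access", "kde", "out_dir", "log_level"}
_NETWORK_KEYS = {"v_walk", "v_bus_kmh", "v_rail_kmh", "dwell_s", "snap_tolerance_m"}
_ACCESS_KEYS = {"thresholds_min", "buffer_width_m"}
_KDE_KEYS = {"radius_m", "cell_size_m"}
_CITY_KEYS = {
    "grid_nx",
    "grid_ny",
    "block_spacing",
    "n_districts",
    "pop_centers",
    "facilities",
    "transit",
    "raster_cell",
}
_INPUT_KEYS = {"walk_edges", "facilities", "districts", "population", "stations", "lines"}


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    city: CityParams | None = None
    inputs: dict | None = None
    network: NetworkParams = field(default_factory=NetworkParams)
    access: AccessConfig = field(default_factory=AccessConfig)
    kde_radius: float = 1000.0
    kde_cell: float = 100.0
    out_dir: str = "out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d: dict = {"seed": self.seed, "out_dir": self.out_dir, "log_level": self.log_level}
        if self.city is not None:
            d["city"] = {
                "grid_nx": self.city.grid_nx,
                "grid_ny": self.city.grid_ny,
                "block_spacing": self.city.block_spacing,
                "n_districts": self.city.n_districts,
                "pop_centers": [list(c) for c in self.city.pop_centers],
                "raster_cell": self.city.raster_cell,
                "facilities": {
                    k: {"n": s.n, "process": s.process, "thomas_parents": s.thomas_parents, "thomas_sd": s.thomas_sd}
                    for k, s in sorted(self.city.facility_specs.items())
                },
                "transit": {
                    k: {
                        "mode": t.mode,
                        "orientation": t.orientation,
                        "corridor": t.corridor,
                        "station_spacing": t.station_spacing,
                    }
                    for k, t in sorted(self.city.transit_specs.items())
                },
            }
        if self.inputs is not None:
            d["inputs"] = dict(sorted(self.inputs.items()))
        d["network"] = {
            "v_walk": self.network.v_walk,
            "v_bus_kmh": self.network.v_bus / KMH,
            "v_rail_kmh": self.network.v_rail / KMH,
            "dwell_s": self.network.dwell,
            "snap_tolerance_m": self.network.snap_tolerance,
        }
        d["access"] = {
            "thresholds_min": list(self.access.thresholds),
            "buffer_width_m": self.access.buffer_width,
        }
        d["kde"] = {"radius_m": self.kde_radius, "cell_size_m": self.kde_cell}
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration only (output location and log level excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build_config(raw: dict) -> RunConfig:
    problems: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level keys: {sorted(unknown)}")
    for key, allowed in (("network", _NETWORK_KEYS), ("access", _ACCESS_KEYS), ("kde", _KDE_KEYS), ("inputs", _INPUT_KEYS)):
        extra = set(raw.get(key) or {}) - allowed
        if extra:
            problems.append(f"unknown keys in {key}: {sorted(extra)}")
    city_extra = set(raw.get("city") or {}) - _CITY_KEYS
    if city_extra:
        problems.append(f"unknown keys in city: {sorted(city_extra)}")
    if raw.get("city") is not None and raw.get("inputs") is not None:
        problems.append("give exactly one of 'city' (synthetic) or 'inputs' (files), not both")

    seed = int(raw.get("seed", 0))

    net_raw = dict(raw.get("network") or {})
    network = None
    try:
        network = NetworkParams(
            v_walk=float(net_raw.get("v_walk", 1.2)),
            v_bus=float(net_raw.get("v_bus_kmh", 40.0)) * KMH,
            v_rail=float(net_raw.get("v_rail_kmh", 70.0)) * KMH,
            dwell=float(net_raw.get("dwell_s", 30.0)),
            snap_tolerance=float(net_raw.get("snap_tolerance_m", 500.0)),
        )
    except ValueError as exc:
        problems.append(f"network: {exc}")

    acc_raw = dict(raw.get("access") or {})
    access = None
    try:
        access = AccessConfig(
            thresholds=tuple(acc_raw.get("thresholds_min", (15.0, 30.0, 60.0))),
            buffer_width=float(acc_raw.get("buffer_width_m", 50.0)),
        )
    except ValueError as exc:
        problems.append(f"access: {exc}")

    kde_raw = dict(raw.get("kde") or {})
    kde_radius = float(kde_raw.get("radius_m", 1000.0))
    kde_cell = float(kde_raw.get("cell_size_m", 100.0))
    if kde_radius <= 0 or kde_cell <= 0:
        problems.append("kde: radius_m and cell_size_m must be positive")

    city = None
    inputs = raw.get("inputs")
    if inputs is None:
        city_raw = dict(raw.get("city") or {})
        try:
            fac = {
                name: FacilitySpec(
                    n=int(s["n"]),
                    process=s.get("process", "uniform"),
                    thomas_parents=int(s.get("thomas_parents", 10)),
                    thomas_sd=float(s.get("thomas_sd", 300.0)),
                )
                for name, s in (city_raw.get("facilities") or {}).items()
            }
            tr = {
                lid: TransitSpec(
                    mode=t["mode"],
                    orientation=t["orientation"],
                    corridor=int(t["corridor"]),
                    station_spacing=float(t["station_spacing"]),
                )
                for lid, t in (city_raw.get("transit") or {}).items()
            }
            kwargs = {k: city_raw[k] for k in ("grid_nx", "grid_ny", "block_spacing", "n_districts", "raster_cell") if k in city_raw}
            if "pop_centers" in city_raw:
                kwargs["pop_centers"] = tuple(tuple(map(float, c)) for c in city_raw["pop_centers"])
            if fac:
                kwargs["facility_specs"] = fac
            if tr:
                kwargs["transit_specs"] = tr
            city = CityParams(seed=seed, **kwargs)
        except (KeyError, ValueError, TypeError) as exc:
            problems.append(f"city: {exc}")
    else:
        missing = {"walk_edges", "facilities", "districts", "population"} - set(inputs)
        if missing:
            problems.append(f"inputs: missing required paths {sorted(missing)}")

    if problems:
        raise ConfigError("; ".join(problems))
    return RunConfig(
        seed=seed,
        city=city,
        inputs=dict(inputs) if inputs is not None else None,
        network=network,
        access=access,
        kde_radius=kde_radius,
        kde_cell=kde_cell,
        out_dir=str(raw.get("out_dir", "out")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration; defaults fill gaps."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    return _build_config(raw)


def config_from_dict(raw: dict) -> RunConfig:
    return _build_config(dict(raw))


def _load_city_from_inputs(inputs: dict, seed: int) -> SyntheticCity:
    walk_edges = mio.read_walk_edges_geojson(inputs["walk_edges"])
    facilities = mio.read_facilities(inputs["facilities"])
    districts = mio.read_polygons_geojson(inputs["districts"])
    population = read_ascii_grid(inputs["population"])
    stations = mio.read_stations_geojson(inputs["stations"]) if inputs.get("stations") else []
    lines = mio.read_transit_lines_csv(inputs["lines"]) if inputs.get("lines") else []
    params = CityParams(seed=seed)  # nominal; geometry comes from the files
    city = SyntheticCity(
        params=params,
        walk_edges=walk_edges,
        districts=districts,
        population=population,
        facilities=facilities,
        transit_lines=lines,
        stations=stations,
    )
    return city


def _city_extent(city: SyntheticCity) -> tuple[float, float, float, float]:
    xs = [p[0] for e in city.walk_edges for p in (e[0], e[1])]
    ys = [p[1] for e in city.walk_edges for p in (e[0], e[1])]
    return (min(xs), min(ys), max(xs), max(ys))


def point_pattern_tables(city: SyntheticCity, kde_radius: float, kde_cell: float) -> dict:
    """Nearest-neighbor, center/ellipse tables and KDE grids for all classes and station modes."""
    extent = _city_extent(city)
    A = (extent[2] - extent[0]) * (extent[3] - extent[1])
    patterns = dict(city.facilities)
    by_mode: dict[str, list] = {}
    for st in city.stations:
        by_mode.setdefault(st.mode, []).append(st.location)
    for mode, locs in sorted(by_mode.items()):
        if len(locs) >= 2:
            patterns[f"{mode}_stations"] = PointPattern(points=locs, label=f"{mode}_stations")
    nn_rows, ellipse_rows, kde_grids = [], [], {}
    for label in sorted(patterns):
        pat = patterns[label]
        res = nn_analysis(pat, A)
        nn_rows.append(
            {
                "class": label,
                "n": res.n,
                "r1bar": res.r1bar,
                "rebar": res.rebar,
                "R": res.R,
                "spatial_structure_type": res.classification,
            }
        )
        cx, cy = mean_center(pat)
        row = {"class": label, "mean_x": cx, "mean_y": cy}
        if pat.n >= 3:
            ell = standard_deviational_ellipse(pat)
            row.update(
                sigma_major=ell.sigma_major,
                sigma_minor=ell.sigma_minor,
                rotation_rad=ell.rotation,
                degenerate=ell.degenerate,
            )
        ellipse_rows.append(row)
        kde_grids[label] = kernel_density(pat, radius=kde_radius, cell_size=kde_cell, extent=extent)
    return {
        "nn_table": pd.DataFrame(nn_rows),
        "ellipse_table": pd.DataFrame(ellipse_rows),
        "kde_grids": kde_grids,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.out_dir``.

    Returns a manifest mapping artifact names to paths. A stage failure
    raises :class:`StageError` naming the stage; artifacts written by
    earlier stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h, seed = config.config_hash, config.seed
    manifest: dict[str, str] = {}

    def _stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    def _write_city():
        city = generate_city(config.city) if config.inputs is None else _load_city_from_inputs(config.inputs, seed)
        mio.write_points_geojson(city.facilities, out / "facilities.geojson")
        mio.write_lines_geojson(city.walk_edges, out / "walk_edges.geojson")
        mio.write_polygons_geojson(city.districts, out / "districts.geojson")
        mio.write_stations_geojson(city.stations, out / "stations.geojson")
        mio.write_transit_lines_csv(city.transit_lines, out / "transit_lines.csv")
        write_ascii_grid(city.population, out / "population.asc")
        manifest.update(
            facilities="facilities.geojson",
            walk_edges="walk_edges.geojson",
            districts="districts.geojson",
            stations="stations.geojson",
            transit_lines="transit_lines.csv",
            population="population.asc",
        )
        return city

    city = _stage("city", _write_city)

    def _pp():
        tables = point_pattern_tables(city, config.kde_radius, config.kde_cell)
        mio.write_table(tables["nn_table"], out / "nn_table.csv", h, seed)
        mio.write_table(tables["ellipse_table"], out / "ellipse_table.csv", h, seed)
        for label, grid in sorted(tables["kde_grids"].items()):
            p = out / f"kde_{label}.asc"
            write_ascii_grid(Raster(origin=grid.origin, cell_size=grid.cell_size, values=grid.values), p)
        manifest.update(nn_table="nn_table.csv", ellipse_table="ellipse_table.csv")
        return tables

    _stage("point_pattern", _pp)

    def _graph():
        g = build_multimodal_graph(city.walk_edges, city.stations, city.transit_lines, config.network)
        mio.write_graph_csv(g, out / "graph_nodes.csv", out / "graph_edges.csv")
        manifest.update(graph_nodes="graph_nodes.csv", graph_edges="graph_edges.csv")
        report = validate_graph(g)
        if report["negative_cost_edges"]:
            raise ValueError("graph has negative edge costs")
        return g

    graph = _stage("network", _graph)

    def _access():
        result = run_accessibility(city, graph, config.access, config.network)
        mio.write_table(result.records, out / "access_records.csv", h, seed)
        mio.write_table(result.class_averages, out / "class_averages.csv", h, seed)
        mio.write_table(result.district_averages, out / "district_averages.csv", h, seed)
        mio.write_isochrones_geojson(result.isochrones, out / "isochrones.geojson")
        run_report = {"config_hash": h, "seed": seed, **result.report, "graph": {
            k: v for k, v in validate_graph(graph).items() if k not in ("orphan_platforms", "negative_cost_edges")
        }}
        (out / "run_report.json").write_text(json.dumps(run_report, indent=1, sort_keys=True) + "\n")
        manifest.update(
            access_records="access_records.csv",
            class_averages="class_averages.csv",
            district_averages="district_averages.csv",
            isochrones="isochrones.geojson",
            run_report="run_report.json",
        )
        return result

    result = _stage("access", _access)

    def _report():
        pivots = report_tables(result.records)
        for name, df in pivots.items():
            mio.write_table(df.reset_index(), out / f"report_{name}.csv", h, seed)
            manifest[f"report_{name}"] = f"report_{name}.csv"
        md = [f"# Accessibility report (config {h}, seed {seed})", ""]
        for name, df in pivots.items():
            md += [f"## {name}", "", format_percent(df).to_markdown(), ""]
        (out / "report.md").write_text("\n".join(md))
        manifest["report_md"] = "report.md"

    _stage("report", _report)
    manifest["config_hash"] = h
    return manifest


def report_tables(records: pd.DataFrame) -> dict:
    """Pivot summaries of an AccessRecord table, averages included.

    Returns raw-fraction pivots: SAR/SPR by district × threshold and by
    class × threshold (each with an ``average`` row), plus the full
    district × class pivots that re-melt losslessly to the records.
    """
    if records.empty:
        raise ValueError("no access records to report")
    class_avg, district_avg = access_averages(records)
    out: dict[str, pd.DataFrame] = {}
    for metric in ("SAR", "SPR"):
        by_class = class_avg.pivot(index="facility_class", columns="threshold_min", values=metric)
        by_class.loc["average"] = by_class.mean(axis=0)
        by_district = district_avg.pivot(index="district", columns="threshold_min", values=metric)
        by_district.loc["average"] = by_district.mean(axis=0)
        full = records.pivot_table(
            index=["district", "facility_class"], columns="threshold_min", values=metric, aggfunc="first"
        )
        out[f"{metric}_by_class"] = by_class
        out[f"{metric}_by_district"] = by_district
        out[f"{metric}_full"] = full
    return out


def toy_config(seed: int = 0, out_dir: str = "out") -> RunConfig:
    """Smallest end-to-end preset: 3×3 street grid, two facility classes, one bus line.

    The coverage buffer is half the block spacing, so a reached street
    serves the blocks beside it (cell centers included by construction).
    """
    city = CityParams(
        seed=seed,
        grid_nx=3,
        grid_ny=3,
        block_spacing=400.0,
        n_districts=2,
        pop_centers=((400.0, 400.0, 5000.0, 300.0),),
        facility_specs={
            "clinic": FacilitySpec(n=6, process="thomas", thomas_parents=2, thomas_sd=150.0),
            "hospital": FacilitySpec(n=2, process="uniform"),
        },
        transit_specs={"B1": TransitSpec("bus", "row", 1, 400.0)},
        raster_cell=100.0,
    )
    return RunConfig(
        seed=seed,
        city=city,
        access=AccessConfig(buffer_width=200.0),
        kde_radius=300.0,
        kde_cell=25.0,
        out_dir=out_dir,
    )


def demo_config(seed: int = 0, out_dir: str = "out") -> RunConfig:
    """The "city" preset: 12×12 grid, five districts, clustered clinics and
    uniform hospitals, one bus and one rail corridor, two population centers.

    Buffer width is half the 400 m block spacing for the same reason as
    :func:`toy_config`.
    """
    return RunConfig(
        seed=seed,
        city=CityParams(seed=seed),
        access=AccessConfig(buffer_width=200.0),
        kde_radius=800.0,
        kde_cell=100.0,
        out_dir=out_dir,
    )


def format_percent(df: pd.DataFrame) -> pd.DataFrame:
    """Render ratio columns as 2-decimal percentages (presentation only)."""
    return df.map(lambda v: f"{100 * v:.2f}%" if isinstance(v, float) else v)
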