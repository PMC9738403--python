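"""Synthetic study regions for exercising the accessibility pipeline.

Real facility, road, transit and population data are typically proprietary
map-provider extracts, so this module generates cities with the statistical
structure the analysis assumes: a grid-like walking street network, bus and
rail corridors with evenly spaced stations, an irregular district partition
(Voronoi), a multi-center population surface, and facility point patterns
spanning the aggregation regimes the nearest-neighbor ratio distinguishes
(clustered Thomas processes, homogeneous Poisson, regular lattices).

All geometry is in planar meters. Generation is fully driven by a seed:
the same :class:`CityParams` always yields a bit-identical city.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .network import Station, TransitLine
from .point_pattern import PointPattern
from .raster import Raster

__all__ = [
    "FacilitySpec",
    "TransitSpec",
    "CityParams",
    "SyntheticCity",
    "make_grid_walk_network",
    "make_population_raster",
    "sample_facilities",
    "make_transit",
    "make_districts",
    "generate_city",
]


@dataclass(frozen=True)
class FacilitySpec:
    """How to sample one facility class.

    ``process`` is ``uniform`` (homogeneous Poisson conditioned on n),
    ``thomas`` (clustered: uniform parents, Gaussian offspring) or
    ``lattice`` (regular square grid, n must be a perfect square).
    """

    n: int
    process: str = "uniform"
    thomas_parents: int = 10
    thomas_sd: float = 300.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("facility count must be >= 2")
        if self.process not in ("uniform", "thomas", "lattice"):
            raise ValueError(f"unknown point process {self.process!r}")
        if self.process == "thomas" and (self.thomas_parents < 1 or self.thomas_sd <= 0):
            raise ValueError("thomas process needs >= 1 parent and positive cluster sd")


@dataclass(frozen=True)
class TransitSpec:
    """One transit line along a grid corridor.

    ``orientation`` is ``row`` (east-west, corridor index = row of grid
    nodes) or ``col`` (north-south); stations sit on the corridor every
    ``station_spacing`` meters starting at its first intersection.
    """

    mode: str
    orientation: str
    corridor: int
    station_spacing: float

    def __post_init__(self) -> None:
        if self.mode not in ("bus", "rail"):
            raise ValueError(f"mode must be bus or rail, got {self.mode!r}")
        if self.orientation not in ("row", "col"):
            raise ValueError(f"orientation must be row or col, got {self.orientation!r}")


@dataclass(frozen=True)
class CityParams:
    """Full parameterisation of a synthetic city.

    ``grid_nx``/``grid_ny`` count street intersections; the extent is the
    grid bounding box, ``(grid_nx-1) × (grid_ny-1)`` blocks of
    ``block_spacing`` meters. ``pop_centers`` are (x, y, total persons,
    Gaussian decay length m) tuples; ``facility_specs`` maps facility
    class name → :class:`FacilitySpec`; ``transit_specs`` maps line id →
    :class:`TransitSpec`.
    """

    seed: int = 0
    grid_nx: int = 20
    grid_ny: int = 20
    block_spacing: float = 400.0
    n_districts: int = 6
    pop_centers: tuple = (
        (2000.0, 2000.0, 400000.0, 1200.0),
        (5600.0, 4400.0, 300000.0, 1000.0),
        (3800.0, 6000.0, 200000.0, 900.0),
    )
    facility_specs: dict = field(
        default_factory=lambda: {
            "tertiary_A": FacilitySpec(n=6, process="thomas", thomas_parents=2, thomas_sd=500.0),
            "general_hospital": FacilitySpec(n=18, process="thomas", thomas_parents=6, thomas_sd=700.0),
            "specialist_hospital": FacilitySpec(n=24, process="thomas", thomas_parents=6, thomas_sd=500.0),
            "community_hospital": FacilitySpec(n=36, process="thomas", thomas_parents=10, thomas_sd=700.0),
            "clinic": FacilitySpec(n=90, process="thomas", thomas_parents=12, thomas_sd=500.0),
            "pharmacy": FacilitySpec(n=150, process="thomas", thomas_parents=15, thomas_sd=400.0),
        }
    )
    transit_specs: dict = field(
        default_factory=lambda: {
            "R1": TransitSpec("rail", "col", 10, 1600.0),
            "R2": TransitSpec("rail", "row", 10, 1600.0),
            "B1": TransitSpec("bus", "row", 5, 800.0),
            "B2": TransitSpec("bus", "col", 5, 800.0),
            "B3": TransitSpec("bus", "row", 15, 800.0),
        }
    )
    raster_cell: float = 200.0

    def __post_init__(self) -> None:
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid needs at least 2x2 intersections")
        if self.block_spacing <= 0:
            raise ValueError("block_spacing must be positive")
        if self.n_districts < 1:
            raise ValueError("n_districts must be positive")
        if self.raster_cell <= 0:
            raise ValueError("raster_cell must be positive")
        w, h = self.width, self.height
        for dim, name in ((w, "width"), (h, "height")):
            if abs(dim / self.raster_cell - round(dim / self.raster_cell)) > 1e-9:
                raise ValueError(f"raster_cell must divide extent {name} ({dim} m)")

    @property
    def width(self) -> float:
        return (self.grid_nx - 1) * self.block_spacing

    @property
    def height(self) -> float:
        return (self.grid_ny - 1) * self.block_spacing

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in meters."""
        return (0.0, 0.0, self.width, self.height)


@dataclass
class SyntheticCity:
    """A generated study region: everything downstream stages consume."""

    params: CityParams
    walk_edges: list  # (p1, p2, length_m) tuples
    districts: dict  # name -> shapely Polygon
    population: Raster
    facilities: dict  # class name -> PointPattern
    transit_lines: list  # TransitLine
    stations: list  # Station

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return self.params.extent

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.extent
        return (x1 - x0) * (y1 - y0)


def make_grid_walk_network(params: CityParams) -> list:
    """Edges of the grid street lattice as (p1, p2, length) tuples.

    A ``grid_nx × grid_ny`` lattice of intersections spaced
    ``block_spacing`` apart has ``2·nx·ny − nx − ny`` edges and is
    connected by construction.
    """
    s = params.block_spacing
    edges = []
    for i in range(params.grid_nx):
        for j in range(params.grid_ny):
            p = (i * s, j * s)
            if i + 1 < params.grid_nx:
                edges.append((p, ((i + 1) * s, j * s), s))
            if j + 1 < params.grid_ny:
                edges.append((p, (i * s, (j + 1) * s), s))
    return edges


def make_population_raster(params: CityParams) -> Raster:
    """Multi-center population surface with per-center mass conservation.

    Each center spreads its total over the grid with Gaussian weights
    ``K(d) = exp(-d²/2L²)`` normalised over all cells, so the raster sum
    equals the sum of requested center totals exactly (up to float
    rounding) regardless of truncation by the extent.
    """
    if not params.pop_centers:
        raise ValueError("need at least one population center")
    nx = round(params.width / params.raster_cell)
    ny = round(params.height / params.raster_cell)
    if nx < 1 or ny < 1:
        raise ValueError("raster has zero cells")
    cx = (np.arange(nx) + 0.5) * params.raster_cell
    cy = (np.arange(ny) + 0.5) * params.raster_cell
    X, Y = np.meshgrid(cx, cy)
    values = np.zeros((ny, nx))
    for x0, y0, total, decay in params.pop_centers:
        if decay <= 0:
            raise ValueError("population decay length must be positive")
        d2 = (X - x0) ** 2 + (Y - y0) ** 2
        K = np.exp(-d2 / (2.0 * decay**2))
        values += total * K / K.sum()
    return Raster(origin=(0.0, 0.0), cell_size=params.raster_cell, values=values)


def sample_facilities(
    spec: FacilitySpec,
    extent: tuple[float, float, float, float],
    seed,
    label: str = "",
) -> PointPattern:
    """Sample one facility class as a point pattern on the extent.

    ``seed`` may be an int or a :class:`numpy.random.Generator`. Thomas
    offspring falling outside the extent are resampled (not clipped) so
    exactly n points are returned; parents are assigned round-robin.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0, y0, x1, y1 = extent
    w, h = x1 - x0, y1 - y0
    if spec.process == "uniform":
        pts = rng.uniform((x0, y0), (x1, y1), size=(spec.n, 2))
    elif spec.process == "lattice":
        m = round(math.sqrt(spec.n))
        if m * m != spec.n:
            raise ValueError(f"lattice process needs a square count, got {spec.n}")
        sx, sy = w / m, h / m
        xs = x0 + (np.arange(m) + 0.5) * sx
        ys = y0 + (np.arange(m) + 0.5) * sy
        X, Y = np.meshgrid(xs, ys)
        pts = np.column_stack([X.ravel(), Y.ravel()])
    else:  # thomas
        parents = rng.uniform((x0, y0), (x1, y1), size=(spec.thomas_parents, 2))
        pts = np.empty((spec.n, 2))
        for k in range(spec.n):
            parent = parents[k % spec.thomas_parents]
            while True:
                p = parent + rng.normal(0.0, spec.thomas_sd, size=2)
                if x0 <= p[0] <= x1 and y0 <= p[1] <= y1:
                    pts[k] = p
                    break
    return PointPattern(points=pts, label=label)


def make_transit(params: CityParams) -> tuple[list, list]:
    """Transit lines and stations along grid corridors.

    A corridor of length L with spacing s carries ``floor(L/s) + 1``
    stations, ordered along the corridor. Lines sharing a corridor cell
    produce co-located stations with distinct ids.
    """
    lines, stations = [], []
    for line_id in sorted(params.transit_specs):
        spec = params.transit_specs[line_id]
        if spec.orientation == "row":
            if not 0 <= spec.corridor < params.grid_ny:
                raise ValueError(f"line {line_id}: row corridor {spec.corridor} outside grid")
            L = params.width
            fixed = spec.corridor * params.block_spacing
            locate = lambda t: (t, fixed)  # noqa: E731
        else:
            if not 0 <= spec.corridor < params.grid_nx:
                raise ValueError(f"line {line_id}: col corridor {spec.corridor} outside grid")
            L = params.height
            fixed = spec.corridor * params.block_spacing
            locate = lambda t: (fixed, t)  # noqa: E731
        if spec.station_spacing > L:
            raise ValueError(f"line {line_id}: station spacing {spec.station_spacing} exceeds corridor length {L}")
        n_st = int(math.floor(L / spec.station_spacing)) + 1
        ids = []
        for k in range(n_st):
            sid = f"{line_id}-S{k}"
            stations.append(
                Station(id=sid, location=locate(k * spec.station_spacing), mode=spec.mode, line_ids=[line_id])
            )
            ids.append(sid)
        lines.append(TransitLine(id=line_id, mode=spec.mode, station_ids=ids))
    return lines, stations


def make_districts(params: CityParams, rng: np.random.Generator) -> dict:
    """Irregular district partition: Voronoi cells of random seeds, clipped to the extent."""
    x0, y0, x1, y1 = params.extent
    seeds = rng.uniform((x0, y0), (x1, y1), size=(params.n_districts, 2))
    extent_box = box(x0, y0, x1, y1)
    if params.n_districts == 1:
        return {"D1": extent_box}
    cells = voronoi_diagram(MultiPoint([Point(p) for p in seeds]), envelope=extent_box)
    districts = {}
    for i, seed_pt in enumerate(seeds):
        for cell in cells.geoms:
            if cell.contains(Point(seed_pt)):
                districts[f"D{i + 1}"] = cell.intersection(extent_box)
                break
        else:  # seed exactly on a cell edge: nearest cell
            best = min(cells.geoms, key=lambda c: c.distance(Point(seed_pt)))
            districts[f"D{i + 1}"] = best.intersection(extent_box)
    return districts


def generate_city(params: CityParams) -> SyntheticCity:
    """Generate the full synthetic city deterministically from ``params.seed``."""
    root = np.random.SeedSequence(params.seed)
    ss_districts, ss_fac = root.spawn(2)
    walk_edges = make_grid_walk_network(params)
    population = make_population_raster(params)
    districts = make_districts(params, np.random.default_rng(ss_districts))
    fac_streams = ss_fac.spawn(len(params.facility_specs))
    facilities = {}
    for (name, spec), ss in zip(sorted(params.facility_specs.items()), fac_streams):
        facilities[name] = sample_facilities(spec, params.extent, np.random.default_rng(ss), label=name)
    transit_lines, stations = make_transit(params)
    return SyntheticCity(
        params=params,
        walk_edges=walk_edges,
        districts=districts,
        population=population,
        facilities=facilities,
        transit_lines=transit_lines,
        stations=stations,
    )
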