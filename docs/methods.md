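# Methods

## The accessibility model

Accessibility is measured by the service-area method under a travel-time
threshold: a location is served by a facility class if it can be reached from
any facility of that class within the threshold along the transport network.
Per district the method reports the service-area ratio `SAR = sa/ta` and the
service-population ratio `SPR = sp/tp`. Both are stored as raw fractions;
percentages appear only in the report layer.

### The multimodal graph

Three layers share one directed graph with symmetric costs (seconds):

- **walk** — every street segment becomes a bidirectional edge with cost
  `length / v_walk`. Endpoints within 0.01 m are merged.
- **access** — each (station, line) pair gets a platform node joined to the
  *nearest street node* by a bidirectional edge costing the snap (Euclidean)
  distance at walking speed. Boarding therefore always pays the true walk to
  the stop rather than teleporting onto the line, and a transfer between two
  lines at the same stop pays both access walks through the shared anchor
  node. Stations farther than `snap_tolerance` (default 500 m) from the
  street network are an error.
- **ride** — consecutive stations of a line are joined by bidirectional edges
  costing `distance / v_mode + dwell`. Distance follows the line's alignment
  polyline when one is given (stations projected onto it; their order must be
  consistent), otherwise the straight line between stations.

Default parameters, with units and provenance in the model:

| parameter        | default    | meaning                                        |
|------------------|------------|------------------------------------------------|
| `v_walk`         | 1.2 m/s    | walking speed                                  |
| `v_bus`          | 40 km/h    | bus in-vehicle speed                           |
| `v_rail`         | 70 km/h    | rail in-vehicle speed                          |
| `dwell`          | 30 s       | per-stop delay impedance on every ride segment |
| `snap_tolerance` | 500 m      | max station/facility distance to the streets   |
| thresholds       | 15/30/60 min | service-area time budgets                    |

Dwell placement was a genuinely open choice: it is embedded in every ride
edge, so boarding at the first station incurs no dwell and a k-segment ride
accumulates k dwell delays. No waiting/headway time is modelled at boarding —
a deliberate simplification of scheduled transit; isochrones are therefore
best-case for transit legs. Station snapping targets the nearest street
*node*, not an interior point of an edge: on grid-like networks the error is
bounded by half a block, and `snap_tolerance` guards pathological inputs.

### Reach and isochrone polygons

Reach is computed by one heap-based Dijkstra expansion seeded with every
facility of the class simultaneously (each source carries an initial cost:
its snap distance at walking speed). This multi-source union per class is
equivalent to per-facility expansion followed by a union, at a fraction of
the cost. Ties in the priority queue break by insertion order, which makes
the expansion — and every artifact downstream — bit-reproducible.

An edge is fully covered when it can be traversed within the budget from
either endpoint; otherwise each reached endpoint covers the edge partially,
the remaining time converted to distance at the edge's own speed. Ride edges
are all-or-nothing: one cannot leave a vehicle between stations. The
isochrone polygon is the union of round-capped buffers over the covered
walk/access portions (plus reached nodes); ride edges contribute
connectivity, never coverage geometry, so a rail line crossing open country
does not paint a served corridor across it.

The buffer width is a reporting parameter, not physics: it states how far
off-street a location may lie and still count as served. The default is 50 m
for arbitrary street data; the synthetic presets use half the block spacing
(200 m), so that a reached street serves the blocks beside it — the analogue
of service polygons spanning the street mesh. The width used is recorded in
every run report, since SAR values are only comparable at equal width.

Population is attached by the cell-center rule: a raster cell belongs to a
district (and to a service area) iff its center point falls inside the
polygon. With cells much smaller than districts the apportionment error is
negligible; area-weighted apportionment was considered and left out to keep
the contract simple and exactly testable.

## Point-pattern statistics

- **Nearest-neighbor ratio.** `R = r̄₁ / r̄_E` with `r̄_E = 0.5·√(A/n)`.
  No edge correction is applied (the plain Clark–Evans form): boundary
  effects bias `R` upward by roughly +0.02 at n = 500 on a square window,
  which the tests absorb. The classification uses a tolerance band of ±0.01
  around 1 (aggregation below, uniform above, random inside) because exact
  equality with 1 never occurs on data. The module takes `A` in m² and all
  distances in m.
- **Quartic kernel density.** Each point spreads mass
  `3(1−(d/r)²)²/(πr²)` over the disk of radius `r`; the surface is the sum
  over points, evaluated at cell centers with no partial-cell weighting, so
  one interior point integrates to 1 and a pattern of n interior points to n.
  No bandwidth selection is provided; `r` is a user parameter.
- **Standard deviational ellipse.** Population (1/n) covariance of the
  centered coordinates, as opposed to the n−1 sample form; axes are one
  standard deviation (no √2 rendering factor — some GIS packages scale the
  drawn ellipse, which affects display, not the eigenstructure). Rotation is
  reported in [0, π) counter-clockwise from east. Collinear patterns return
  `sigma_minor = 0` with a degeneracy flag instead of raising.

## The synthetic-city generator

The generator emulates the statistical structure of a polycentric mountain
city's data, not its geography:

- a `grid_nx × grid_ny` lattice of street intersections (default 20×20,
  400 m blocks, i.e. a 7.6 km square);
- bus/rail corridors along grid rows/columns with stations every 800/1600 m;
- an irregular district partition: Voronoi cells of seeded random points
  clipped to the extent (default 6 districts);
- a population surface summing per-center Gaussian kernels, each normalized
  over the grid so the raster total equals the requested center totals
  exactly (default three centers, 900 000 persons);
- facility classes as point processes. Defaults follow the empirical
  ordering of Chinese urban medical tiers — few, strongly clustered
  tertiary-A hospitals up to many, widely spread pharmacies — all Thomas processes with class-specific parent counts and
  cluster spreads. Thomas offspring falling outside the window are resampled
  so class counts are exact; a `lattice` process (R ≈ 2) and `uniform`
  (CSR, R ≈ 1) span the remaining regimes for calibration.

What it does *not* emulate: real street-network irregularity (dead ends,
rivers, bridges), one-way streets, timetable effects, facility capacity, or
any correlation between facility siting and population beyond what clustering
induces by chance. Passing tests therefore demonstrate the correctness of the
computations and the qualitative regime ordering, not quantitative agreement
with any real city.

## Numerical choices

- All coordinates are planar meters; no geographic CRS enters the core.
- Walk endpoints quantized to 0.01 m before node merging.
- SAR/SPR are clamped to [0, 1] against float rounding in polygon
  intersection areas (overshoots are of order 1e-16).
- Polygon nesting across thresholds is exact by construction (coverage is
  monotone in budget); tests verify containment under a 1e-6 m buffer to
  absorb arc discretization of the round caps.
- Degenerate inputs: empty source lists, districts of zero area and
  non-positive budgets raise; districts with zero population yield SPR = NaN
  (missing), never 0.
- Problem sizes in the test-suite and acceptance runs (an 8×8-block city for
  integration tests, the 20×20 preset for acceptance, 200 CSR replicates of
  n = 500) were chosen so the full suite completes in well under a minute
  while keeping Monte-Carlo error far inside the asserted bands.

## Known limitations

- No demand-side (resident-origin) isochrones; service is measured from
  facilities outward.
- No 2SFCA/gravity/potential accessibility measures.
- No GTFS or timetable ingestion; headways and waiting are absent.
- The ESRI ASCII grid is the only raster format (single band, square cells).
- Nearest-neighbor statistics are uncorrected for edges; KDE has no
  bandwidth selection; the mean center is unweighted.
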