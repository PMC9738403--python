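import numpy as np
import pytest

from medaccess.network import NetworkParams, Station, TransitLine, build_multimodal_graph
from medaccess.pipeline import toy_config
from medaccess.synthetic_city import CityParams, generate_city


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231204)


@pytest.fixture(scope="session")
def small_city():
    """A compact six-district city used by the slower integration tests."""
    from medaccess.synthetic_city import FacilitySpec, TransitSpec

    params = CityParams(
        seed=11,
        grid_nx=8,
        grid_ny=8,
        n_districts=4,
        raster_cell=200.0,
        pop_centers=((1000.0, 1000.0, 50000.0, 800.0), (2000.0, 2000.0, 30000.0, 600.0)),
        facility_specs={
            "clinic": FacilitySpec(n=24, process="thomas", thomas_parents=4, thomas_sd=300.0),
            "hospital": FacilitySpec(n=5, process="uniform"),
        },
        transit_specs={
            "B1": TransitSpec("bus", "row", 3, 800.0),
            "R1": TransitSpec("rail", "col", 4, 1600.0),
        },
    )
    return generate_city(params)


@pytest.fixture(scope="session")
def toy_cfg(tmp_path_factory):
    return toy_config(seed=5, out_dir=str(tmp_path_factory.mktemp("toy")))


@pytest.fixture()
def line_graph():
    """Walk path 0-1-2 (400 m blocks) with one 2-station bus line anchored at nodes 0 and 2."""
    walk_edges = [((0.0, 0.0), (400.0, 0.0), 400.0), ((400.0, 0.0), (800.0, 0.0), 400.0)]
    stations = [
        Station(id="S0", location=(0.0, 0.0), mode="bus", line_ids=["B"]),
        Station(id="S1", location=(800.0, 0.0), mode="bus", line_ids=["B"]),
    ]
    lines = [TransitLine(id="B", mode="bus", station_ids=["S0", "S1"])]
    params = NetworkParams()
    return build_multimodal_graph(walk_edges, stations, lines, params), params
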