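import numpy as np
import pytest

from dermaflux import hemodynamics, transport
from dermaflux.cli import default_shear_zone_rois
from dermaflux.synth import CELL_PIXEL_SIZE_UM


@pytest.fixture(scope="session")
def default_net():
    return hemodynamics.default_network()


@pytest.fixture(scope="session")
def default_solution(default_net):
    return hemodynamics.solve_flow(default_net)


@pytest.fixture(scope="session")
def coarse_domain(default_net):
    """Bundled geometry rasterized on a 128-cell-wide grid (46.875 um)."""
    return transport.default_domain(46.875, network=default_net)


@pytest.fixture(scope="session")
def vessel_mask_5um(default_net):
    """Vessel mask at cell-imaging resolution (5 um/px)."""
    return transport.rasterize_network(default_net, CELL_PIXEL_SIZE_UM)


@pytest.fixture(scope="session")
def shear_zones():
    return default_shear_zone_rois()


def two_node_layout(diameter_um=500.0, length_um=10_000.0):
    return {
        "nodes": {"a": [0.0, 0.0], "b": [length_um, 0.0]},
        "segments": [
            {"id": "s", "node_a": "a", "node_b": "b",
             "diameter_um": diameter_um, "length_um": length_um}
        ],
        "inlet": "a",
        "outlet": "b",
    }


@pytest.fixture
def single_segment_net():
    return hemodynamics.build_network(two_node_layout())
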