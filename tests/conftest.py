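"""Shared fixtures: one synthetic bundle and derived panels per session."""

import numpy as np
import pytest
from hypothesis import settings

from oatcompass import marker_linkage, simulate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return simulate.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def bundle(config):
    return simulate.simulate_truth_set(config)


@pytest.fixture(scope="session")
def linkage_panel(bundle, config):
    markers, truth = simulate.simulate_linkage_panel(bundle, config)
    return markers, truth


@pytest.fixture(scope="session")
def linkage_placements(bundle, linkage_panel):
    markers, _ = linkage_panel
    placements, rejects = marker_linkage.place_markers(markers, bundle.genome_A)
    return placements, rejects


@pytest.fixture(scope="session")
def hexaploid_panel():
    cfg = simulate.SimulationConfig(seed=2, translocation_spec=("Mrg01", 60.0, "AE3"))
    return simulate.simulate_hexaploid_panel(cfg)


@pytest.fixture(scope="session")
def hexaploid_placements(hexaploid_panel):
    panel = hexaploid_panel
    plc_a, _ = marker_linkage.place_markers(panel.markers, panel.bundle.genome_A)
    plc_c, _ = marker_linkage.place_markers(panel.markers, panel.bundle.genome_C)
    return plc_a, plc_c


@pytest.fixture
def rng():
    return np.random.default_rng(0)
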