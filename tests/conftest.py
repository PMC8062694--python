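"""Shared fixtures: a small synthetic world and its search database."""

import pytest

from darkpep.dbbuild import build_search_db
from darkpep.simulate import SimulationConfig, generate_world


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=1,
        n_coding_genes=12,
        n_pseudogenes=5,
        n_lncrnas=4,
        n_repeat_copies=3,
    )


@pytest.fixture(scope="session")
def world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def db(world):
    return build_search_db(world.known_proteome, world.annotation)


@pytest.fixture(scope="session")
def default_world():
    """World under the default study conditions (used by FDR-level tests)."""
    cfg = SimulationConfig(seed=7)
    return cfg, generate_world(cfg)
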