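import numpy as np
import pytest

from flocknet import (SimConfig, build_gbi, simulate_population,
                      simulate_stream)


@pytest.fixture(scope="session")
def small_config():
    """One room, five 3-chick families, five days: fast but structured."""
    return SimConfig(n_families=5, room_split=(5,), brood_sizes=(3, 3, 3, 3, 3),
                     n_cort=8, n_control=7, n_days=5, seed=11)


@pytest.fixture(scope="session")
def small_roster(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_stream(small_config, small_roster):
    return simulate_stream(small_roster, small_config)


@pytest.fixture(scope="session")
def small_gbi(small_roster, small_stream):
    _, truth = small_stream
    return build_gbi(truth, small_roster)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
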