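import numpy as np
import pytest

from cmlsim import (
    EvolutionParams,
    ExchangeParams,
    HierarchyConfig,
    build_level_rates,
    make_toy_hierarchy,
)


@pytest.fixture(scope="session")
def default_config():
    return HierarchyConfig()


@pytest.fixture(scope="session")
def default_rates(default_config):
    return build_level_rates(default_config)


@pytest.fixture(scope="session")
def default_evolution():
    """The printed progressive parameter combination."""
    return EvolutionParams(mu=9e-4, s_bcrabl=0.67)


@pytest.fixture(scope="session")
def default_exchange():
    return ExchangeParams()


@pytest.fixture()
def toy_rates():
    """4-level toy: 3 mitotic levels with gamma=2, 64 cells/day output."""
    return make_toy_hierarchy(n_levels=4, n_hsc=8, gamma=2.0, output=64.0)


@pytest.fixture()
def toy_exchange():
    return ExchangeParams(mature_blood_target=64.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230403)
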