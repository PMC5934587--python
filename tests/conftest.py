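import numpy as np
import pytest

from barcodeid import HKY_COI_DEFAULT, MarketConfig, sim_market_scenario


@pytest.fixture(scope="session")
def coi_model():
    return HKY_COI_DEFAULT


@pytest.fixture(scope="session")
def small_scenario():
    """A compact market scenario shared by several integration tests."""
    cfg = MarketConfig(n_species=6, n_genera=2, n_queries=8, n_sites=650,
                       refs_per_species=2, seed=42)
    return sim_market_scenario(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
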