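import numpy as np
import pytest

from adaptrial import SimConfig, simulate_trial


@pytest.fixture(scope="session")
def case1_interim_config() -> SimConfig:
    """Table-2-style favorable scenario: high survival, low event rate."""
    return SimConfig(hazard_range=(0.02, 0.03), event_rate_range=(0.05, 0.10))


@pytest.fixture(scope="session")
def case1_dataset(case1_interim_config):
    """One seeded trial under the favorable scenario."""
    rng = np.random.default_rng(20240115)
    return simulate_trial(case1_interim_config, rng)
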