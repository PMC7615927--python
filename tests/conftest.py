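import numpy as np
import pytest

from macrodiv.simulate import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused by pipeline-level tests."""
    cfg = SyntheticConfig(
        n_species=40,
        families=8,
        cluster_count=5,
        spatial_effect={"MEM4": 0.199, "MEM12": -0.185},
        seed=123,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
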