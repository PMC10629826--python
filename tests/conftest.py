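import numpy as np
import pytest

from bfatools.simulate import SimulationConfig, simulate_pool


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_pool():
    """A small noisy pool shared by read-level tests."""
    cfg = SimulationConfig(
        n_lineages=20,
        n_neutral=5,
        n_timepoints=3,
        read_depth=3000,
        bottleneck_size=None,
        n_replicates=1,
        n_environments=2,
        seed=42,
    )
    truth, counts = simulate_pool(cfg)
    return cfg, truth, counts
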