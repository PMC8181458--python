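import numpy as np
import pytest

from admixpower import load_config, simulate_repetition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_sim():
    """One standard-setting repetition (N=1000, 1000 loci, 100 causal)."""
    cfg = load_config()
    return simulate_repetition(cfg, 42)


@pytest.fixture(scope="session")
def standard_cfg():
    return load_config()
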