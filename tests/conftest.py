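import numpy as np
import pytest

from dupdiverge.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A scaled-down generative configuration for fast end-to-end tests."""
    return SimConfig(n_high=30, n_low=30, n_conditions=40, n_codons=60, seed=7)
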