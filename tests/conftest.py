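import numpy as np
import pytest

from molbit import DesignConfig, init_barcodes, synthetic_pore_model


@pytest.fixture(scope="session")
def pore_model():
    return synthetic_pore_model(6, seed=1)


@pytest.fixture(scope="session")
def small_pore_model():
    return synthetic_pore_model(4, seed=2)


@pytest.fixture(scope="session")
def barcode_state_8(pore_model):
    """A small valid design state shared by design/classify tests."""
    config = DesignConfig(n_barcodes=8)
    return init_barcodes(config, pore_model, "random", rng=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
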