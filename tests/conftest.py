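import numpy as np
import pytest

from microverse.chemistry import load_reference_universe


@pytest.fixture(scope="session")
def universe():
    return load_reference_universe()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
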