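import numpy as np
import pytest

from sparkcell import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
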