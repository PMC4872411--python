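import numpy as np
import pytest

from fcnet.synth import fixture_graphs


@pytest.fixture(scope="session")
def graphs():
    """Named small fixture graphs with known topology."""
    return fixture_graphs()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
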