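import numpy as np
import pytest

from connage import make_parcellation, make_ground_truth


@pytest.fixture(scope="session")
def parc100():
    return make_parcellation(100)


@pytest.fixture(scope="session")
def parc15():
    """Small parcellation with one 3-node network (VN) for formula checks."""
    sizes = {"VN": 3, "SMN": 2, "LN": 2, "FPN": 2, "DMN": 2, "DAN": 2, "VAN": 2}
    return make_parcellation(15, network_sizes=sizes)


@pytest.fixture(scope="session")
def truth100(parc100):
    return make_ground_truth(parc100)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
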