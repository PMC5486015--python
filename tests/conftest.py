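import numpy as np
import pytest

from flexprofiler.synthetic_data import build_toy_protein


@pytest.fixture(scope="session")
def helix12():
    return build_toy_protein(12, "helix")


@pytest.fixture(scope="session")
def helix60():
    return build_toy_protein(60, "helix")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
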