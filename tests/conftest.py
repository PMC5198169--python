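import numpy as np
import pytest

from blsomhgt.composition import build_index


@pytest.fixture(scope="session")
def index4():
    return build_index(4)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
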