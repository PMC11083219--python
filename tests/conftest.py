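import numpy as np
import pytest

from mosaicfocus.mosaic_crystal import get_preset


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def m012():
    return get_preset("m012")
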