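import logging

import numpy as np
import pytest


@pytest.fixture(autouse=True)
def _quiet_fallback_warnings(caplog):
    """Cluster-fallback warnings are expected in small-image tests."""
    logging.getLogger("segdict.reconstruction").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
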