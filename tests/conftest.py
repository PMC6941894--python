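import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_qc_warnings(caplog):
    """QC warnings (replicate spread, efficiency range) are expected on noisy
    synthetic data; keep them out of the test output."""
    logging.getLogger("weaklink.qpcr").setLevel(logging.ERROR)
    logging.getLogger("weaklink.kinetics").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
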