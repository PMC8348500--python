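import numpy as np
import pytest
from hypothesis import settings

from ecisbarrier import (
    BASELINE_PARAMETERS,
    DEFAULT_ELECTRODE,
    FREQUENCY_GRID,
    AcquisitionProtocol,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def electrode():
    return DEFAULT_ELECTRODE


@pytest.fixture(scope="session")
def baseline():
    return BASELINE_PARAMETERS


@pytest.fixture(scope="session")
def grid():
    return np.asarray(FREQUENCY_GRID)


@pytest.fixture(scope="session")
def coarse_protocol():
    """Half-hour sampling over the full study window; keeps fits cheap."""
    return AcquisitionProtocol(sampling_interval_s=1800.0, replicates_per_group=2)
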