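import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def regular_ts():
    """Seven observations at times 1..7, the canonical regular fixture."""
    from smtrend import TimeSeries

    return TimeSeries(np.arange(1.0, 8.0), np.array([1.0, 2, 3, 4, 5, 6, 7]))


@pytest.fixture
def irregular_ts():
    """The canonical uneven-steps fixture: times (1,3,4,5,6,8,9)."""
    from smtrend import TimeSeries

    return TimeSeries(
        np.array([1.0, 3, 4, 5, 6, 8, 9]),
        np.array([2.0, 4, 3, 5, 7, 6, 8]),
    )
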