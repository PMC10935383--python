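import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    from wearmiss import AnalysisConfig

    return AnalysisConfig()


@pytest.fixture
def minute_times():
    """A day of 1/min timestamps starting on a Thursday morning."""

    def make(n, start="2019-03-07T09:00:00"):
        return np.datetime64(start) + (np.arange(n) * 60).astype("timedelta64[s]")

    return make
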