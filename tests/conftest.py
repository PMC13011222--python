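import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slopefill import SyntheticSpec, TimeSeries, generate_series

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def volatile_series() -> TimeSeries:
    """A default-parameter synthetic year of daily concentrations."""
    return generate_series(SyntheticSpec())


@pytest.fixture
def short_volatile_series() -> TimeSeries:
    return generate_series(SyntheticSpec(length=120, seed=11))


def make_series(values, start=0) -> TimeSeries:
    return TimeSeries.from_values(np.asarray(values, dtype=float), start=start)
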