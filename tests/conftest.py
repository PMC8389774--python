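import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from entroconv import EnergySeries, GaussianSpec, gaussian_stream

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def big_gaussian_15():
    """10^6 i.i.d. Gaussian energies with sigma = 15 kJ/mol at 300 K."""
    return gaussian_stream(GaussianSpec(sigma=15.0), 1_000_000, seed=2024)


@pytest.fixture()
def toy_series():
    return EnergySeries(np.array([-1.0, 1.0, -1.0, 1.0]), temperature=300.0)
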