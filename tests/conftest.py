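import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# Property tests must behave identically on every run.
settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20190207)


@pytest.fixture(scope="session")
def rho_c_grid():
    """Moderate (rho, c) grid covering the analytically relevant region."""
    rhos = np.linspace(-0.9, 0.9, 7)
    cuts = np.linspace(-2.0, 2.0, 9)
    return [(float(r), float(c)) for r in rhos for c in cuts]
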