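import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from enzact import AssayCondition, ThermoLandscape


@pytest.fixture
def default_template():
    """Landscape constants used throughout the reference simulations:
    dGT = -40 kJ/mol, alpha = 0.5, k1_0 = k2_0 = 1, T = 298.15 K."""
    return ThermoLandscape(dG1=0.0, dGT=-40.0)


@pytest.fixture
def standard_cond():
    return AssayCondition(S=10.0, ET=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
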