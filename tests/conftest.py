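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
def mono_grid():
    """2000 s monomerization window at 2 s spacing."""
    return np.arange(0.0, 2000.1, 2.0)


@pytest.fixture
def dissoc_grid():
    """18,000 s dissociation window at 6 s spacing."""
    return np.arange(0.0, 18_000.1, 6.0)


@pytest.fixture
def titration_grid():
    """12-point titrant series from 7 pM to 15 nM (log-spaced)."""
    return np.geomspace(7e-12, 15e-9, 12)
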