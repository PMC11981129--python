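import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import picsim
from picsim import (build_default_model, build_model, ModelConfig,
                    characterize_membrane, run_voltage_clamp_biramp,
                    run_current_clamp_biramp)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def membrane_props(default_model):
    """The full membrane battery on the default cell (shared: ~10 s)."""
    return characterize_membrane(default_model)


@pytest.fixture(scope="session")
def default_vclamp_trace(default_model):
    """Default bi-ramp voltage clamp on the default cell."""
    return run_voltage_clamp_biramp(default_model)


@pytest.fixture(scope="session")
def default_iclamp_trace(default_model):
    """Default bi-ramp current clamp on the default cell."""
    return run_current_clamp_biramp(default_model)
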