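import numpy as np
import pytest

from cardiofit import (
    ParameterScaling,
    SimulationSettings,
    get_model,
    pace_to_steady_state,
)
from cardiofit.experiment_io import generate_synthetic_target
from cardiofit.ga import SimulationContext


@pytest.fixture(scope="session")
def reduced_model():
    return get_model("reduced")


@pytest.fixture(scope="session")
def flagship_model():
    return get_model("faber-rudy")


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture(scope="session")
def truth():
    return ParameterScaling()


@pytest.fixture(scope="session")
def base_state(reduced_model, settings, truth):
    """Baseline steady-state snapshot of the reduced model (1800 paced beats)."""
    return pace_to_steady_state(reduced_model, truth, settings=settings)


@pytest.fixture(scope="session")
def synth_target(reduced_model, settings, truth):
    """Noise-free combined synthetic target at truth scalings = 1."""
    return generate_synthetic_target(reduced_model, truth, settings=settings)


@pytest.fixture(scope="session")
def context(reduced_model, synth_target, settings):
    return SimulationContext(reduced_model, synth_target.base_state, settings)
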