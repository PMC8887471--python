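import numpy as np
import pytest

from rpacircuit import (StepExperiment, defaults_v1, simulate_step)


@pytest.fixture(scope="session")
def ideal_leakfree():
    return defaults_v1("ideal_linear", leak_free=True)


@pytest.fixture(scope="session")
def ideal_leaky():
    return defaults_v1("ideal_linear")


@pytest.fixture(scope="session")
def hill_defaults():
    return defaults_v1("hill")


@pytest.fixture(scope="session")
def step_2_200():
    return StepExperiment(2.0, 200.0, np.arange(0.0, 24.0 + 1e-9, 0.1))


@pytest.fixture(scope="session")
def step_2_200_long():
    # long enough for the integral-feedback mode to relax to numerical zero
    return StepExperiment(2.0, 200.0, np.arange(0.0, 60.0 + 1e-9, 0.25))


@pytest.fixture(scope="session")
def ideal_step_trajs(ideal_leakfree, step_2_200_long):
    """Cached leak-free ideal-linear step response (used by many tests)."""
    return simulate_step(step_2_200_long, ideal_leakfree)
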