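import numpy as np
import pytest

from arousalctl import ObservationParams, StateNoiseParams, generate_profile


@pytest.fixture
def unit_params() -> ObservationParams:
    """Unit observation model: gamma=0, tonic r = x + N(0, 1)."""
    return ObservationParams(
        gamma=0.0, tonic_intercept=0.0, tonic_slope=1.0, tonic_noise_var=1.0
    )


@pytest.fixture
def default_noise() -> StateNoiseParams:
    return StateNoiseParams(
        process_var=0.005, gain_walk_var=5e-5, disturbance_walk_var=3e-4
    )


@pytest.fixture
def profile():
    return generate_profile(101, profile_id="P1")


@pytest.fixture
def rng():
    return np.random.default_rng(np.random.SeedSequence(12345))
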