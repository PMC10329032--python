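import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_session():
    """A 3-gesture synthetic session small enough for unit tests."""
    from hdsemg.synth import generate_session, make_separable_benchmark

    spec = make_separable_benchmark(
        3, 0.0, seed=7, mu_per_gesture=2, repetition_duration=1.0,
        rest_duration=0.5, n_repetitions=3, grid=(8, 8), noise_std=0.02)
    return generate_session(spec)


@pytest.fixture(scope="session")
def tiny_windowed(small_session):
    from hdsemg.preprocess import (NormalizationConfig, WindowSpec,
                                   preprocess_session)

    session, _ = small_session
    return preprocess_session(session, NormalizationConfig(),
                              WindowSpec(64, 32, 8, 8))
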