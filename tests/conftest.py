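import numpy as np
import pytest
from dataclasses import replace

from gaitseg.synthetic_gait import (
    DEFAULT_PROFILES,
    generate_cohort,
    generate_session,
)


def noise_free(profile):
    """Copy of a profile with (numerically) zero sensor noise."""
    return replace(profile, noise_sd_gyro=1e-12, noise_sd_accel=1e-12)


NOISE_FREE_PROFILES = {k: noise_free(p) for k, p in DEFAULT_PROFILES.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def walking_session():
    """20 annotated walking cycles, default noise, no bias."""
    return generate_session(protocol=[("WK", 20)], seed=8)


@pytest.fixture(scope="session")
def clean_walking_session():
    """Noise-free walking session: deterministic template only."""
    return generate_session(
        protocol=[("WK", 12)], seed=3, profiles=NOISE_FREE_PROFILES
    )


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects with a short 4-activity protocol (fast tests)."""
    protocol = [("WK", 8), ("SA", 6), ("RUN", 8), ("SD", 6)]
    return generate_cohort(3, protocol=protocol, seed=11)
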