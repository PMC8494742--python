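import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octaquant import PhantomConfig, generate_phantom_case

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom_case():
    """One default phantom (full study geometry, default eye motion)."""
    return generate_phantom_case(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def identity_motion_case():
    """Phantom with identity eye motion, for analytic territory checks."""
    return generate_phantom_case(PhantomConfig(seed=2, motion=np.eye(3)))
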