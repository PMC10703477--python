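import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motionlab import synthgen
from motionlab.core import Element, PointTrajectory, build_element

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gait_bundle():
    """Dummy gait fixture at generator defaults (stride 7, stance 4 s)."""
    return synthgen.gen_dummy_gait()


@pytest.fixture(scope="session")
def antiphase_bundle():
    return synthgen.gen_antiphase_pair()


@pytest.fixture(scope="session")
def mixture_bundle():
    return synthgen.gen_sine_mixture()


@pytest.fixture
def zigzag_element():
    """Small 2-POI planar element with non-trivial geometry."""
    t = np.linspace(0.0, 1.0, 11)
    a = PointTrajectory("a", t, np.column_stack([t, np.sin(2 * np.pi * t)]))
    b = PointTrajectory("b", t, np.column_stack([t + 1.0, np.cos(2 * np.pi * t)]))
    return build_element("zigzag", [a, b])
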