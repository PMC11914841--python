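import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line_shape():
    from vrmotorlab.kinematics import LineShape

    return LineShape(p0=(0.0, 0.0, 0.0), p1=(0.3, 0.0, 0.0))


@pytest.fixture
def circle_shape():
    from vrmotorlab.kinematics import CircleShape

    return CircleShape(c=(0.0, 0.0, 0.0), r=0.1, n=(0.0, 0.0, 1.0))


@pytest.fixture
def clean_line_trajectory(line_shape):
    """Single-submovement, noise-free minimum-jerk line trace at 60 Hz."""
    from vrmotorlab.synthetic import TrajectoryGenSpec, generate_trajectory

    return generate_trajectory(TrajectoryGenSpec(shape=line_shape, duration_s=2.0))
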