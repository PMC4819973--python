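import numpy as np
import pytest
from hypothesis import settings

from usnav.geometry import PoseStream, RigidTransform, TimedPose

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def random_rigid(rng: np.random.Generator, tmax: float = 50.0) -> RigidTransform:
    """A uniformly random rotation with a bounded random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    return RigidTransform(rot, rng.uniform(-tmax, tmax, 3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def rz90() -> RigidTransform:
    return RigidTransform.from_axis_angle([0, 0, 1], 90.0)


def make_stream(timestamps, poses) -> PoseStream:
    return PoseStream([TimedPose(t, p) for t, p in zip(timestamps, poses)])
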