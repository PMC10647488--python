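import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydromocap.geometry import CameraModel, Distortion, Intrinsics, RigidTransform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ideal_camera():
    """Pinhole camera without distortion, identity pose."""
    return CameraModel(
        "ideal",
        Intrinsics(1000.0, 1000.0, 1352.0, 760.0),
        Distortion(),
        RigidTransform.identity("world"),
    )


@pytest.fixture
def gopro_camera():
    """Wide-angle 2.7K camera with the default barrel distortion."""
    return CameraModel(
        "gopro",
        Intrinsics(800.0, 800.0, 1351.5, 759.5),
        Distortion(k1=-0.25, k2=0.05),
        RigidTransform.identity("world"),
    )


def random_rigid_transform(rng, source="a", target="b", max_translation=2000.0):
    """A random proper rigid transform (helper shared across test modules)."""
    rotation = Rotation.random(rng=rng).as_matrix()
    translation = rng.uniform(-max_translation, max_translation, 3)
    return RigidTransform(rotation, translation, source_frame=source, target_frame=target)
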