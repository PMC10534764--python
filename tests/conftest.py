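import numpy as np
import pytest

from daras.pipeline import RunConfig, make_single_action_scripts
from daras.synth import Camera, NoiseModel, SyntheticScript, make_session
from daras.taxonomy import DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def taxonomy():
    return DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def tiny_camera():
    return Camera(width=24, height=24, focal_px=20.0)


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseModel.silent()


@pytest.fixture(scope="session")
def small_session(tiny_camera):
    """A 50-frame walking-then-idle session with mild noise."""
    script = SyntheticScript(
        entries=(("walking", 20), ("none_of_the_above", 30)),
        noise=NoiseModel(depth_sigma_mm=2.0, joint_sigma_m=0.002,
                         dropout_prob=0.0),
        seed=7,
        camera=tiny_camera,
    )
    return make_session(script)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
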