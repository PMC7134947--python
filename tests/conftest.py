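import numpy as np
import pytest

from hyperphen.envi import HyperCube, Interleave, Unit
from hyperphen.simulate import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """4x5 pixels, 10 bands, radiance unit."""
    return HyperCube(
        data=rng.uniform(0.0, 2.0, size=(4, 5, 10)),
        wavelengths_nm=400.0 + 10.0 * np.arange(10),
        unit=Unit.RADIANCE,
        camera_id="test",
        interleave=Interleave.BIL,
    )


@pytest.fixture
def noiseless_scene_config():
    return SceneConfig(lines=60, samples=60, noise_sd=0.0, seed=7)
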