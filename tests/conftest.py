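import numpy as np
import pytest

from eyolo.smear_synth import SmearSceneConfig, generate_scenes

# small network schedule used by fast structural/training tests
TINY_NET = {"base_channels": [16, 24, 32, 32, 40],
            "base_depths": [1, 2, 2, 2, 2],
            "head_channels": 24, "epsilon": 0.01, "deformable": True}


@pytest.fixture(scope="session")
def default_scenes_500():
    """500 scenes from the default generator config (the calibration set)."""
    return generate_scenes(SmearSceneConfig(seed=20260922), 500)


@pytest.fixture(scope="session")
def small_scenes():
    """A handful of 128x128 scenes for functional tests."""
    return generate_scenes(
        SmearSceneConfig(image_size=(128, 128), seed=11), 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
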