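import numpy as np
import pytest

from save_hsi import (SpectralCalibration, load_colorchecker,
                      simulate_camera)


@pytest.fixture(scope="session")
def patches():
    return load_colorchecker()


@pytest.fixture(scope="session")
def patches_with_rgb(patches):
    rgb = simulate_camera(patches, seed=0)
    return patches.with_camera_rgb(rgb)


@pytest.fixture(scope="session")
def fitted(patches_with_rgb):
    """Closed-loop calibration fitted on the packaged chart with the
    noise-free simulated camera."""
    return SpectralCalibration(patches_with_rgb).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
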