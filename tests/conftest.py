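import numpy as np
import pytest

from tidemark import synthetic
from tidemark.raster import ClassRaster, GridGeometry


@pytest.fixture(scope="session")
def small_config():
    """64x64 three-epoch landscape used by most integration tests."""
    return synthetic.LandscapeConfig(n_rows=64, n_cols=64, n_epochs=3, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return synthetic.simulate_landscape_series(small_config)


@pytest.fixture(scope="session")
def calibration():
    return synthetic.default_calibration()


@pytest.fixture(scope="session")
def zero_noise_scene(small_truth, calibration):
    """First-epoch scene rendered without spectral noise: exactly separable."""
    return synthetic.render_scene(
        small_truth.class_maps[0], small_truth.signatures, calibration,
        noise_sd_scale=0.0, seed=11, epoch=small_truth.config.epochs[0])


@pytest.fixture
def checkerboard():
    """8x8 alternating mangrove / non-mangrove map."""
    codes = np.indices((8, 8)).sum(axis=0) % 2 + 1
    return ClassRaster(codes.astype(np.uint8), GridGeometry(8, 8))
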