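import numpy as np
import pytest

from leafdist.cube import SpectralCube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cube(rng, n_rows=5, n_cols=5, n_bands=10, calibrated=True):
    """Small random reflectance cube spanning the full sensor range."""
    wavelengths = np.linspace(450.0, 900.0, n_bands)
    values = rng.uniform(0.05, 0.95, size=(n_rows, n_cols, n_bands))
    return SpectralCube(values, wavelengths, calibrated=calibrated)


@pytest.fixture
def small_cube(rng):
    return random_cube(rng)
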