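import numpy as np
import pytest

from clearcount3d.io import Volume3D
from clearcount3d.synthetic import BackgroundField, Cell, SyntheticScene, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_volume():
    """Constant-intensity volume: the restoration identity case."""
    return Volume3D(np.full((12, 12, 12), 50.0), spacing=(3.0, 3.26, 3.26))


@pytest.fixture
def one_cell_scene():
    """Small quiet scene with a single bright cell, no noise."""
    return SyntheticScene(
        shape=(48, 48, 48),
        cells=[Cell(center=(24.0, 24.0, 24.0), radius=4.0, amplitude=5.0)],
        background=BackgroundField(level=100.0, length_scale=16.0, amplitude=0.0),
        noise_sd_frac=0.0,
        seed=0,
    )


@pytest.fixture
def gaussian_blob_volume():
    """Pure isotropic Gaussian blob of scale s = 3 on a 48³ grid (no background)."""
    s = 3.0
    coords = np.arange(48) - 23.5
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    r2 = zz**2 + yy**2 + xx**2
    vol = Volume3D(np.exp(-r2 / (2 * s**2)), spacing=(1.0, 1.0, 1.0))
    return vol, s, np.sqrt(r2)
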