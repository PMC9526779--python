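import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petinsert import SystemModel, VolumeImage, VoxelGrid

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)


@pytest.fixture()
def small_grid():
    """32x32x3 grid with 2 mm in-plane spacing (toy projector scale)."""
    return VoxelGrid((32, 32, 3), (2.0, 2.0, 2.8))


@pytest.fixture()
def small_model(small_grid):
    return SystemModel.for_grid(small_grid, n_angles=48)


@pytest.fixture()
def disc_image(small_grid):
    """Uniform 10 kBq/mL disc of radius 20 mm, all slices."""
    g = small_grid
    cx, cy, _ = g.center_mm()
    xx, yy = np.meshgrid(g.centers(0) - cx, g.centers(1) - cy, indexing="ij")
    disc = (xx**2 + yy**2) <= 20.0**2
    vals = np.where(disc, 10_000.0, 0.0)[:, :, None] * np.ones((1, 1, g.dims[2]))
    return VolumeImage(g, vals, "Bq/mL")


@pytest.fixture()
def water_mu(small_grid, disc_image):
    """Water attenuation inside the disc support."""
    from petinsert.system import MU_WATER_511KEV

    vals = np.where(disc_image.values > 0, MU_WATER_511KEV, 0.0)
    return VolumeImage(small_grid, vals, "1/cm")
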