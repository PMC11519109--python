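import numpy as np
import pytest

from diagqm import ImageVolume, PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def desk_phantom_config() -> PhantomConfig:
    """Small, fast phantom grid used across the suite."""
    return PhantomConfig(
        volume_shape=(64, 64, 8), voxel_spacing=(1.5, 1.5, 4.0), seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(desk_phantom_config):
    return generate_cohort(desk_phantom_config, 12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def ramp_volume() -> ImageVolume:
    """A smooth 16x16x2 ramp volume with non-trivial structure."""
    x, y, z = np.meshgrid(
        np.linspace(0, 1, 16), np.linspace(0, 1, 16), np.arange(2), indexing="ij"
    )
    return ImageVolume(0.2 + 0.6 * x + 0.2 * y + 0.05 * z, spacing=(1.0, 1.0, 3.0))
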