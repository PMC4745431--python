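import numpy as np
import pytest

from spinereg import make_test_scene
from spinereg.phantom import PhantomSpec


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-condition scene: 128^3 phantom, 96x96 views, noise sigma 2."""
    return make_test_scene(noise_sigma=2.0, seed=1, step=1.0)


@pytest.fixture(scope="session")
def clean_scene():
    """Same phantom imaged without noise."""
    return make_test_scene(noise_sigma=0.0, seed=1, step=1.0)


@pytest.fixture(scope="session")
def small_spec():
    """A 32^3 phantom small enough for brute-force per-voxel oracles."""
    return PhantomSpec(
        volume_size=(32, 32, 32),
        spacing=(1.0, 1.0, 1.0),
        body_radius=9.0,
        body_half_height=7.0,
        shell_thickness=2.0,
        canal_radius=3.0,
        canal_center_y=10.0,
        marker_centers=np.array([[10.0, 0.0, 5.0], [-10.0, 2.0, -4.0], [0.0, -10.0, 0.0]]),
        marker_radius=1.5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
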