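import numpy as np
import pytest

from perfusionkit import ChannelGeometry, FluidProperties
from perfusionkit.synthetic import PatchSimConfig


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def geometry():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def chamber():
    """The 10 mm x 10 mm tissue chamber with a consistent cross-section."""
    return ChannelGeometry(
        width_Ly_m=0.01, height_Lz_m=0.01, cross_section_area_Ac_m2=1e-4
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_patch_cfg():
    """Fast patch scene: 512 px frame, 3.2 mm patch, nine spheroids."""
    return PatchSimConfig(
        frame_px=512,
        matrix_radius_um=1800.0,
        n_spheroids=9,
        n_holes=3,
        hole_fraction=0.12,
        seed=0,
    )
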