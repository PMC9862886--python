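import numpy as np
import pytest

from fhnquant.mask_io import LabelVolume
from fhnquant.phantom_sim import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def iso_phantom():
    """Default phantom (R=25, theta=45, d=15) on the 0.8 mm grid."""
    return generate_phantom(PhantomSpec(), case_id="iso-default")


@pytest.fixture(scope="session")
def coarse_phantom():
    """Default geometry on the fast 1.6 mm grid."""
    return generate_phantom(PhantomSpec(grid="coarse"), case_id="coarse-default")


@pytest.fixture(scope="session")
def theta0_phantom():
    """Lesion-free phantom (theta = 0) on the fast grid."""
    return generate_phantom(
        PhantomSpec(wedge_half_angle_deg=0.0, grid="coarse"), case_id="theta0"
    )


@pytest.fixture()
def tiny_volume():
    """Minimal hand-built volume: a 2-voxel lesion inside a small bone block."""
    labels = np.zeros((8, 8, 8), dtype=np.int16)
    labels[2:6, 2:6, 2:6] = 1
    labels[3:5, 3:5, 5] = 2
    return LabelVolume(case_id="tiny", labels=labels, spacing=(1.0, 1.0, 1.0))
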