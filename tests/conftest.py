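import numpy as np
import pytest

from spheremap import UnfoldOptions, VoxelSpacing
from spheremap.phantoms import PhantomSpec, make_spheroid_stack


@pytest.fixture(scope="session")
def sphere_phantom():
    """Uniform spherical shell, radius 20 um, centered in a 64^3 volume."""
    spec = PhantomSpec(
        shape=(64, 64, 64),
        semi_axes_um=(20.0, 20.0, 20.0),
        shell_thickness_um=2.0,
        seed=0,
    )
    return make_spheroid_stack(spec)


@pytest.fixture(scope="session")
def checker_phantom():
    """Checkerboard shell: 4 latitude x 8 longitude tiles."""
    spec = PhantomSpec(
        shape=(64, 64, 64),
        semi_axes_um=(22.0, 22.0, 22.0),
        shell_thickness_um=2.0,
        pattern=("checkerboard", 4, 8),
    )
    return make_spheroid_stack(spec)


@pytest.fixture
def small_options():
    return UnfoldOptions(map_width=120, map_height=60)


@pytest.fixture(scope="session")
def anisotropic_spacing():
    return VoxelSpacing(dx=0.3, dy=0.3, dz=0.8)
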