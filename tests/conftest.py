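import numpy as np
import pytest

from bonefem import (
    DamageLaw,
    ElasticConstants,
    VoxelSpecimen,
    generate_hollow_cylinder,
    voxels_to_mesh,
)


@pytest.fixture(scope="session")
def constants():
    return ElasticConstants()


@pytest.fixture(scope="session")
def law():
    return DamageLaw()


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """Single 1 mm cube element."""
    spec = VoxelSpecimen(np.ones((1, 1, 1), dtype=bool), spacing=1.0)
    return voxels_to_mesh(spec)


@pytest.fixture(scope="session")
def tube_mesh():
    """Ideal (noise-free) hollow cylinder at coarse test resolution."""
    spec = generate_hollow_cylinder(
        outer_diameter=3.5,
        wall_thickness=0.5,
        height=5.0,
        voxel_size=0.25,
        eccentricity=0.0,
        thickness_noise_sd=0.0,
        seed=0,
    )
    return voxels_to_mesh(spec)


@pytest.fixture(scope="session")
def small_tube_mesh():
    """Small irregular specimen for fast fracture runs."""
    spec = generate_hollow_cylinder(
        outer_diameter=2.0,
        wall_thickness=0.5,
        height=1.5,
        voxel_size=0.25,
        eccentricity=0.15,
        thickness_noise_sd=0.03,
        seed=0,
    )
    return voxels_to_mesh(spec)


def random_symmetric(rng, scale=0.05):
    a = rng.normal(0.0, scale, size=(3, 3))
    return (a + a.T) / 2.0


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
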