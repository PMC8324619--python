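"""Shared fixtures: a desk-scale phantom and one cached noisy acquisition.

The mini phantom keeps the full structure of the study object (six hot
spheres on a ring, cold lung insert, background VOI) on a coarse 4.42 mm
grid so reconstruction-level tests run in seconds.
"""

import numpy as np
import pytest

from qspect import (
    CLINICAL_PROTOCOL,
    PhantomSpec,
    PhysicsModel,
    VoxelGrid,
    build_phantom,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def mini_grid():
    return VoxelGrid(shape=(64, 64, 12), voxel_size=4.42)


@pytest.fixture(scope="session")
def mini_spec():
    return PhantomSpec(
        body_width=200.0,
        body_height=160.0,
        body_corner_radius=40.0,
        body_length=44.0,
        sphere_ring_radius=40.0,
        lung_insert_diameter=30.0,
        background_voi_volume=20.0,
        background_voi_center=(0.0, 55.0, 0.0),
    )


@pytest.fixture(scope="session")
def mini_real(mini_spec, mini_grid):
    return build_phantom(mini_spec, mini_grid)


@pytest.fixture(scope="session")
def mini_physics():
    return PhysicsModel()


@pytest.fixture(scope="session")
def mini_acq(mini_real, mini_physics):
    """One noisy clinical-protocol acquisition of the mini phantom."""
    return simulate_acquisition(
        mini_real, CLINICAL_PROTOCOL, mini_physics, seed=7, dtype=np.float32
    )


@pytest.fixture(scope="session")
def mini_acq_noisefree(mini_real, mini_physics):
    return simulate_acquisition(
        mini_real, CLINICAL_PROTOCOL, mini_physics, noise=False, dtype=np.float64
    )
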