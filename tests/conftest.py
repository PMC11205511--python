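import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cellshape3d as cs

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sphere10():
    return cs.voxelize(cs.sphere(10))


@pytest.fixture(scope="session")
def sphere15():
    return cs.voxelize(cs.sphere(15))


@pytest.fixture(scope="session")
def sphere20():
    return cs.voxelize(cs.sphere(20))


@pytest.fixture(scope="session")
def box953():
    return cs.voxelize(cs.box(9, 5, 3))


@pytest.fixture(scope="session")
def ellipsoid842():
    return cs.voxelize(cs.ellipsoid(8, 4, 2))


@pytest.fixture(scope="session")
def dumbbell_region():
    return cs.voxelize(cs.dumbbell(8, 8, 12))


@pytest.fixture(scope="session")
def sphere15_params(sphere15):
    return cs.basic_params(sphere15)


@pytest.fixture(scope="session")
def sphere15_descriptors(sphere15_params):
    return cs.compute_descriptors(sphere15_params)


def make_region(mask, spacing=(1, 1, 1), origin=(0, 0, 0), label=1, time_index=None):
    return cs.VoxelRegion(
        mask=np.asarray(mask, dtype=bool),
        spacing=spacing,
        origin=origin,
        label=label,
        time_index=time_index,
    )


@pytest.fixture
def unit_cube_mesh():
    """Hand-built closed unit cube: 8 vertices, 12 outward triangles."""
    verts = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    tris = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # z = 0
            [4, 5, 6], [4, 6, 7],  # z = 1
            [0, 1, 5], [0, 5, 4],  # y = 0
            [1, 2, 6], [1, 6, 5],  # x = 1
            [2, 3, 7], [2, 7, 6],  # y = 1
            [3, 0, 4], [3, 4, 7],  # x = 0
        ]
    )
    return cs.SurfaceMesh(vertices=verts, triangles=tris)
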