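import numpy as np
import pytest

from ddsd.voxel import VolumetricModel


def random_connected_solid(rng: np.random.Generator, max_voxels: int = 200,
                           dims: int = 16) -> VolumetricModel:
    """Random 26-connected voxel solid grown by a lattice random walk."""
    grid = np.zeros((dims, dims, dims), dtype=np.uint8)
    pos = np.array([dims // 2] * 3)
    grid[tuple(pos)] = 1
    n_target = int(rng.integers(20, max_voxels + 1))
    filled = 1
    while filled < n_target:
        step = rng.integers(-1, 2, size=3)
        nxt = np.clip(pos + step, 1, dims - 2)
        if not grid[tuple(nxt)]:
            grid[tuple(nxt)] = 1
            filled += 1
        pos = nxt
    return VolumetricModel(grid=grid, spacing=1.0)


@pytest.fixture(scope="session")
def rod_model():
    """1-voxel-wide straight rod, 8 voxels long."""
    grid = np.zeros((12, 5, 5), dtype=np.uint8)
    grid[2:10, 2, 2] = 1
    return VolumetricModel(grid=grid, spacing=1.0)


@pytest.fixture(scope="session")
def block_model():
    """Solid 5x5x5 block."""
    grid = np.zeros((7, 7, 7), dtype=np.uint8)
    grid[1:6, 1:6, 1:6] = 1
    return VolumetricModel(grid=grid, spacing=1.0)


@pytest.fixture(scope="session")
def ball_model():
    from ddsd.synth import make_ball

    return make_ball(radius=9.0, dims=24)


@pytest.fixture(scope="session")
def icosphere():
    import trimesh

    return trimesh.creation.icosphere(subdivisions=3, radius=1.0)
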