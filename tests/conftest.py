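import numpy as np
import pytest

from biopsy3d import BinaryMask


def mask_of(data, voxel_edge_um: float = 2.0) -> BinaryMask:
    return BinaryMask(data=np.asarray(data, dtype=bool), voxel_edge_um=voxel_edge_um)


def solid_cube(edge: int, grid: int, voxel_edge_um: float = 2.0) -> BinaryMask:
    """A solid ``edge``-cube centered in a ``grid``-cube of background."""
    data = np.zeros((grid,) * 3, dtype=bool)
    lo = (grid - edge) // 2
    data[lo:lo + edge, lo:lo + edge, lo:lo + edge] = True
    return mask_of(data, voxel_edge_um)


def random_mask(rng, dims=(12, 12, 12), density: float = 0.5,
                voxel_edge_um: float = 2.0) -> BinaryMask:
    return mask_of(rng.random(dims) < density, voxel_edge_um)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
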