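import numpy as np
import pytest

from contactome.adjacency import ThresholdSpec
from contactome.condensation import run_condensation
from contactome.fixtures import (
    PlantedAdjacencySpec,
    TubePhantomSpec,
    make_planted_adjacency,
    make_tube_phantom,
)


@pytest.fixture(scope="session")
def planted():
    """Canonical 4-block planted adjacency (4 x 10 nodes, seed 7)."""
    return make_planted_adjacency(PlantedAdjacencySpec(seed=7))


@pytest.fixture(scope="session")
def planted_trace(planted):
    A, _ = planted
    return run_condensation(A)


@pytest.fixture(scope="session")
def two_tube_phantom():
    """Two radius-5 tubes with a 1-px gap between their disks, 4 slices."""
    spec = TubePhantomSpec(
        n_slices=4,
        image_shape=(32, 48),
        tubes=[(1, (15, 12), 5.0), (2, (15, 23), 5.0)],
        pixel_size=4.5,
        z_spacing=30.0,
    )
    return make_tube_phantom(spec)


@pytest.fixture(scope="session")
def three_tube_phantom():
    """Three tubes with known gaps: 1-3 close, 2 far from both."""
    spec = TubePhantomSpec(
        n_slices=3,
        image_shape=(40, 64),
        tubes=[(1, (20, 10), 4.0), (2, (20, 52), 4.0), (3, (20, 21), 4.0)],
        pixel_size=4.5,
        z_spacing=30.0,
    )
    return make_tube_phantom(spec)


@pytest.fixture
def threshold_2px():
    return ThresholdSpec(distance_nm=9.0, distance_px=2)


def double_loop_modularity(A: np.ndarray, comm: np.ndarray) -> float:
    """Independent oracle: literal double-sum weighted modularity."""
    deg = A.sum(axis=1)
    two_m = deg.sum()
    s = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if comm[i] == comm[j]:
                s += A[i, j] - deg[i] * deg[j] / two_m
    return s / two_m
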