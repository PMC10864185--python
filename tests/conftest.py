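import numpy as np
import pytest

from tcncommunity import CellMap, SynthConfig, simulate_map


@pytest.fixture
def tiny_map() -> CellMap:
    return CellMap(
        cell_ids=["a", "b", "c"],
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]]),
        cell_types=["B", "T", "B"],
    )


@pytest.fixture
def square_map() -> CellMap:
    return CellMap(
        cell_ids=[f"c{i}" for i in range(4)],
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        cell_types=["B", "T", "B", "T"],
    )


@pytest.fixture
def small_comp_map():
    """A 300-cell compartmentalized map with hard region boundaries."""
    cfg = SynthConfig(n_cells=300, geometry="compartmentalized",
                      boundary_softness=0.0, seed=42)
    return simulate_map(cfg)


def two_triangles():
    """Adjacency of two disconnected 3-cliques."""
    A = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[i, j] = A[j, i] = 1.0
    return A


def four_cycle():
    A = np.zeros((4, 4))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
        A[i, j] = A[j, i] = 1.0
    return A
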