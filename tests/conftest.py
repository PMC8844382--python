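import numpy as np
import pytest

from phagenet.io import HostRangeMatrix
from phagenet.network import build_pbin


def matrix_from_host_sets(host_sets, n_bacteria, phage_names=None):
    """Build a HostRangeMatrix from per-phage host index lists."""
    phage_names = phage_names or [f"p{j+1}" for j in range(len(host_sets))]
    values = np.zeros((n_bacteria, len(host_sets)))
    for j, hosts in enumerate(host_sets):
        values[list(hosts), j] = 1.0
    bacteria = tuple(f"b{i+1}" for i in range(n_bacteria))
    return HostRangeMatrix(bacteria, tuple(phage_names), values)


@pytest.fixture
def worked_matrix():
    """6 bacteria x 4 phages: A={b1..b4}, B={b1,b2,b5}, C={b3,b4,b6}, D={b5,b6}.

    Hand-derived reference: no strain has a unique lyser, the greedy picks
    {A, B, C}, and the optimal cover has size 2 ({A,D} and {B,C} both work).
    """
    return matrix_from_host_sets(
        [[0, 1, 2, 3], [0, 1, 4], [2, 3, 5], [4, 5]], 6, list("ABCD")
    )


@pytest.fixture
def worked_pbin(worked_matrix):
    return build_pbin(worked_matrix)


@pytest.fixture
def identity_matrix():
    def make(n):
        return HostRangeMatrix(
            tuple(f"b{i+1}" for i in range(n)),
            tuple(f"p{j+1}" for j in range(n)),
            np.eye(n),
        )

    return make


def random_binary_matrix(rng, n_bacteria, n_phages, fill):
    values = (rng.random((n_bacteria, n_phages)) < fill).astype(float)
    return HostRangeMatrix(
        tuple(f"b{i+1}" for i in range(n_bacteria)),
        tuple(f"p{j+1}" for j in range(n_phages)),
        values,
    )
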