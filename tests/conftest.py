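import numpy as np
import pytest


def euclidean_distmat(points):
    """Plain (non-periodic) Euclidean distance matrix for test point clouds."""
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def unit_square_distmat():
    return euclidean_distmat([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
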