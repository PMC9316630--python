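import numpy as np
import pytest

from hcid import DistanceMatrix, IntervalMatrix


def random_interval_matrix(rng, n, j, degenerate_frac=0.0):
    """A seeded random IntervalMatrix; optionally zero out some radii."""
    centers = rng.normal(0.0, 3.0, size=(n, j))
    radii = np.abs(rng.normal(1.0, 0.8, size=(n, j)))
    if degenerate_frac:
        mask = rng.random(size=(n, j)) < degenerate_frac
        radii[mask] = 0.0
    return IntervalMatrix(centers, radii)


def random_distance_matrix(rng, n):
    """A seeded random symmetric matrix with zero diagonal (no exact ties)."""
    a = rng.random((n, n))
    d = (a + a.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, metric_tag="generic")


@pytest.fixture
def rng():
    return np.random.default_rng(20220703)


@pytest.fixture
def toy_distance():
    """3 leaves A, B, C with d(A,B)=1, d(A,C)=4, d(B,C)=5."""
    d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    return DistanceMatrix(d, metric_tag="generic", obs_ids=["A", "B", "C"])
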