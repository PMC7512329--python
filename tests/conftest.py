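import numpy as np
import pytest

from nestmax import IncidenceMatrix, NestedSpec, perfect_nested


@pytest.fixture
def tiny_matrix():
    """The 2x2 worked example: B = {{1,1},{1,0}}."""
    return IncidenceMatrix.from_array([[1, 1], [1, 0]])


@pytest.fixture
def checker_matrix():
    return IncidenceMatrix.from_array([[1, 0], [0, 1]])


@pytest.fixture(scope="session")
def nested_30x20():
    """A mid-size isocline-consistent perfectly nested matrix."""
    return perfect_nested(NestedSpec(30, 20, 0.25))


@pytest.fixture
def rng():
    return np.random.default_rng(20181008)


def random_incidence(rng, n, m, fill=0.5):
    """Random binary matrix with no empty rows/columns (rejection sampled)."""
    while True:
        entries = (rng.random((n, m)) < fill).astype(np.uint8)
        if entries.sum(axis=1).min() > 0 and entries.sum(axis=0).min() > 0:
            return IncidenceMatrix.from_array(entries)
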