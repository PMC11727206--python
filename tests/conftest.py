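import numpy as np
import pytest


@pytest.fixture
def line4():
    """Four collinear 1-D points {0, 1, 2, 3}; balanced optimum D_K = 1."""
    return np.array([[0.0], [1.0], [2.0], [3.0]])


@pytest.fixture
def duplicated_pairs():
    """Every point duplicated exactly twice: a zero-discrepancy split exists."""
    rng = np.random.default_rng(7)
    base = rng.normal(size=(6, 3))
    return np.repeat(base, 2, axis=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
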