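import numpy as np
import pytest

from sigdendro.io import DataMatrix, standardize_rows


@pytest.fixture
def three_point_matrix() -> DataMatrix:
    """Columns a=(0,0), b=(3,4), c=(6,8): distances d(a,b)=5, d(b,c)=5, d(a,c)=10."""
    return DataMatrix(
        np.array([[0.0, 3.0, 6.0], [0.0, 4.0, 8.0]]),
        row_ids=["v1", "v2"],
        col_ids=["a", "b", "c"],
    )


@pytest.fixture
def small_standardized() -> DataMatrix:
    """A fixed 2x3 standardized matrix for permutation-enumeration checks."""
    rng = np.random.default_rng(42)
    X = DataMatrix(rng.normal(size=(2, 3)))
    return standardize_rows(X)


@pytest.fixture
def well_separated():
    """Two clusters of 100 samples each, means 0 and +10 on 8 variables."""
    rng = np.random.default_rng(7)
    left = rng.standard_normal((8, 100))
    right = rng.standard_normal((8, 100)) + 10.0
    X = DataMatrix(np.hstack([left, right]))
    truth = np.array([1] * 100 + [2] * 100)
    return X, truth
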