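import warnings

import numpy as np
import pytest

from assemblage.io_core import BinaryMatrix, FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array([[2, 2, 0], [1, 3, 4], [5, 0, 1]])
    return FeatureTable(counts, ["s1", "s2", "s3"], ["t1", "t2", "t3"])


def random_binary(rng, n_rows, n_cols, p=0.4):
    """Random BinaryMatrix without degenerate rows/columns."""
    m = (rng.random((n_rows, n_cols)) < p).astype(np.uint8)
    for i in np.nonzero(m.sum(1) == 0)[0]:
        m[i, rng.integers(n_cols)] = 1
    for j in np.nonzero(m.sum(0) == 0)[0]:
        m[rng.integers(n_rows), j] = 1
    return BinaryMatrix(
        m, [f"t{i}" for i in range(n_rows)], [f"s{j}" for j in range(n_cols)]
    )


def random_table(rng, n_samples, n_taxa, max_count=20):
    counts = rng.integers(0, max_count, size=(n_samples, n_taxa))
    counts[:, 0] += 1  # keep every sample non-empty
    return FeatureTable(
        counts, [f"s{i}" for i in range(n_samples)], [f"t{j}" for j in range(n_taxa)]
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
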