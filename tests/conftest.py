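import numpy as np
import pytest
import scipy.sparse as sp

from ra3.preprocess import PeakSet, RawCountMatrix


def make_counts(dense, seed_ids=True) -> RawCountMatrix:
    """Wrap a dense integer array (peaks x cells) as a RawCountMatrix."""
    dense = np.asarray(dense)
    p, n = dense.shape
    peaks = PeakSet(
        np.array(["chr1"] * p, dtype=object),
        np.arange(p) * 1000,
        np.arange(p) * 1000 + 500,
    )
    cells = np.array([f"cell_{j}" for j in range(n)], dtype=object)
    return RawCountMatrix(sp.csr_matrix(dense), peaks, cells)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_counts(rng):
    """A 40-peak x 30-cell sparse count matrix with no empty cells/peaks."""
    dense = rng.poisson(0.8, size=(40, 30))
    dense[0] += 1  # guard: no zero-depth cell
    dense[:, 0] += 1
    while (dense.sum(axis=0) == 0).any() or ((dense != 0).sum(axis=1) == 0).any():
        dense += rng.poisson(0.2, size=dense.shape)
    return make_counts(dense)
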