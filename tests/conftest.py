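import numpy as np
import pytest
import scipy.sparse as sp

from epiconv.matrix_io import BinaryMatrix


def make_binary(dense, peak_ids=None, barcodes=None, batches=None) -> BinaryMatrix:
    """BinaryMatrix from a dense 0/1 array (peaks x cells)."""
    dense = np.asarray(dense, dtype=np.int8)
    n_peaks, n_cells = dense.shape
    if peak_ids is None:
        peak_ids = [f"p{i}" for i in range(n_peaks)]
    if barcodes is None:
        barcodes = [f"c{j}" for j in range(n_cells)]
    return BinaryMatrix(sp.csc_matrix(dense), np.array(peak_ids, dtype=object),
                        np.array(barcodes, dtype=object),
                        None if batches is None else np.array(batches, dtype=object))


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def random_binary(rng):
    """60 peaks x 25 cells random binary matrix, every cell non-empty."""
    dense = (rng.random((60, 25)) < 0.3).astype(np.int8)
    dense[0, dense.sum(axis=0) == 0] = 1
    return make_binary(dense)
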