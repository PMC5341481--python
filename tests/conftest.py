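import numpy as np
import pytest

import nucleomark as nm


@pytest.fixture(scope="session")
def toy10():
    """Default toy model shrunk to a 10-bp window (nearest-neighbour, lam=0)."""
    return nm.default_toy_model(window_length=10)


@pytest.fixture(scope="session")
def toy20():
    return nm.default_toy_model(window_length=20)


@pytest.fixture(scope="session")
def all_seqs6():
    """All 4^6 length-6 sequences as an encoded (4096, 6) matrix."""
    codes = np.arange(4**6)
    mat = np.empty((4**6, 6), dtype=np.uint8)
    for j in range(6):
        mat[:, 5 - j] = (codes >> (2 * j)) & 3
    return mat
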