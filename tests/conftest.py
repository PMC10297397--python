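import numpy as np
import pytest
from hypothesis import settings

from padicwc import PadicGrid

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def grid_2_3() -> PadicGrid:
    return PadicGrid(2, 3)


@pytest.fixture
def grid_3_2() -> PadicGrid:
    return PadicGrid(3, 2)


def direct_convolve(grid: PadicGrid, w: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Independent brute-force oracle for the Haar-weighted group convolution:
    (w * phi)_k = p^-l sum_i w_{(k-i) mod p^l} phi_i."""
    n = grid.size
    out = np.zeros(n)
    for k in range(n):
        acc = 0.0
        for i in range(n):
            acc += w[(k - i) % n] * phi[i]
        out[k] = acc / n
    return out
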