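import numpy as np
import pytest

from texton3d import filterbank as fb


@pytest.fixture(scope="session")
def small_bank():
    """Compact bank whose kernels fit a 16^3 volume (extents <= 13)."""
    return fb.build_filter_bank(n_orientations=6, scales=[(1, 1, 2)], gauss_log_sigma=2)


@pytest.fixture(scope="session")
def default_bank():
    return fb.build_filter_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_correlate(vol: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct-sum correlation oracle: symmetric padding + windowed inner products."""
    hz, hy, hx = (d // 2 for d in kernel.shape)
    vp = np.pad(vol, ((hz, hz), (hy, hy), (hx, hx)), mode="symmetric")
    win = np.lib.stride_tricks.sliding_window_view(vp, kernel.shape)
    return np.einsum("zyxabc,abc->zyx", win, kernel)
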