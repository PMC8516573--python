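"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest


def brute_local_stats(image: np.ndarray, n: int):
    """Per-pixel windowed mean/population variance via explicit padding and
    a double loop — the independent oracle for the sliding-window path."""
    arr = np.asarray(image, dtype=np.float64)
    # np.pad "symmetric" repeats the edge pixel, matching scipy's "reflect"
    padded = np.pad(arr, n, mode="symmetric")
    h, w = arr.shape
    mean = np.empty_like(arr)
    var = np.empty_like(arr)
    for i in range(h):
        for j in range(w):
            win = padded[i : i + 2 * n + 1, j : j + 2 * n + 1]
            mean[i, j] = win.sum() / (2 * n + 1) ** 2
            var[i, j] = ((win - mean[i, j]) ** 2).sum() / (2 * n + 1) ** 2
    return mean, var


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Truncated, renormalized discrete Gaussian (direct evaluation)."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
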