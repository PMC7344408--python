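import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_rgb(rng):
    """Factory for random uint8 RGB images."""

    def make(h=32, w=32):
        return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)

    return make


@pytest.fixture
def random_plane(rng):
    """Factory for random {0,1} planes."""

    def make(h=32, w=32, p=0.5):
        return (rng.random((h, w)) < p).astype(np.uint8)

    return make


def boundary_oracle(mask):
    """Mask pixels with at least one 4-neighbour outside the mask."""
    m = np.asarray(mask).astype(bool)
    pad = np.pad(m, 1)
    interior = pad[:-2, 1:-1] & pad[2:, 1:-1] & pad[1:-1, :-2] & pad[1:-1, 2:]
    return m & ~interior


def brute_force_lowpass_quantize(plane, kernel, threshold=0.5):
    """Independent reference: explicit padded convolution, ties to 1."""
    k = np.asarray(kernel, dtype=float)
    r = k.shape[0] // 2
    padded = np.pad(np.asarray(plane, dtype=float), r, mode="symmetric")
    h, w = np.asarray(plane).shape
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(k.shape[0]):
                for b in range(k.shape[1]):
                    acc += k[a, b] * padded[i + a, j + b]
            out[i, j] = 1 if acc >= threshold - 1e-9 else 0
    return out
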