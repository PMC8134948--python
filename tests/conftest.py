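import numpy as np
import pytest

from stepfinder import Trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_trace(rng):
    """Pure white Gaussian noise, no steps."""
    return Trace(rng.normal(0.0, 1.0, 400))


@pytest.fixture
def two_level_trace():
    """Noiseless two-plateau trace [0,0,4,4]."""
    return Trace(np.array([0.0, 0.0, 4.0, 4.0]))


def brute_force_sse(x):
    """Two-pass SSE about the mean; independent of the prefix-sum path."""
    x = np.asarray(x, float)
    return float(((x - x.mean()) ** 2).sum())


def brute_force_best_split(x):
    """Exhaustive O(n^2) SSE minimisation over every split position."""
    x = np.asarray(x, float)
    best = None
    total = brute_force_sse(x)
    for i in range(1, len(x)):
        sse = brute_force_sse(x[:i]) + brute_force_sse(x[i:])
        gain = total - sse
        if best is None or gain > best[1] + 1e-12:
            best = (i, gain)
    return best


def brute_force_best_split_sad(x):
    """Exhaustive total-absolute-deviation minimisation (median levels)."""
    x = np.asarray(x, float)

    def sad(v):
        return float(np.abs(v - np.median(v)).sum())

    total = sad(x)
    best = None
    for i in range(1, len(x)):
        gain = total - (sad(x[:i]) + sad(x[i:]))
        if best is None or gain > best[1] + 1e-12:
            best = (i, gain)
    return best
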