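import numpy as np
import pytest

from brainrgin.graph_construction import FNCMatrix


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        ix = it.multi_index
        xp = x.copy()
        xp[ix] += eps
        xm = x.copy()
        xm[ix] -= eps
        g[ix] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fnc(rng: np.random.Generator, n: int, t: int = 60) -> FNCMatrix:
    """A valid random correlation matrix from a random signal."""
    x = rng.normal(size=(n, t))
    return FNCMatrix(np.corrcoef(x))


@pytest.fixture
def fnc6(rng):
    return random_fnc(rng, 6)
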