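import numpy as np
import pytest

from mtcgan import default_catalog, easy_config, generate


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_corpus(catalog):
    """40 separable sentences plus ground truth."""
    return generate(easy_config(n_sentences=40, rng_seed=3), catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar-valued f at x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return g
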