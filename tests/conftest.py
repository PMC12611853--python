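import numpy as np
import pytest

from noduleseg.synthetic import PhantomConfig, generate_phantom, scaled_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-size (128 px) phantom with nodules."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    """A 64-px phantom for network-level tests."""
    return generate_phantom(scaled_config(64, seed=3))


def numgrad(fn, arr, eps=1e-3):
    """Central finite differences of a scalar-valued fn wrt arr (in place)."""
    g = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        fp = fn()
        arr[i] = orig - eps
        fm = fn()
        arr[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
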