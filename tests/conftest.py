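import numpy as np
import pytest

from m3seg.config import get_preset


def central_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Numerical gradient of scalar-valued ``f()`` w.r.t. array ``x`` (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_close(tensor, numerical, rtol=1e-5):
    scale = np.abs(numerical).max() + 1e-12
    assert tensor.grad is not None, "no gradient reached this tensor"
    np.testing.assert_allclose(tensor.grad / scale, numerical / scale, atol=rtol)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    return get_preset("tiny")


@pytest.fixture(scope="session")
def tiny_model():
    """A built (untrained) tiny model shared across shape/contract tests."""
    from m3seg.model import build_model

    return build_model(get_preset("tiny"), in_channels=1, seed=7)
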