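import numpy as np
import pytest

from glsegnet.autograd import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_gradient(fn, arr: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar fn w.r.t. a float64 array."""
    arr = np.asarray(arr, dtype=np.float64)
    grad = np.zeros_like(arr)
    flat = arr.ravel()
    gflat = grad.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn(arr)
        flat[i] = orig - eps
        fm = fn(arr)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return grad


def autodiff_gradient(fn, arr: np.ndarray) -> np.ndarray:
    t = Tensor(np.asarray(arr, dtype=np.float64), requires_grad=True)
    out = fn(t)
    out.backward()
    return t.grad


def assert_gradcheck(fn_tensor, fn_scalar, arr, rtol=1e-4, atol=1e-6, eps=1e-5):
    """Compare autodiff and finite-difference gradients of a scalar function."""
    ana = autodiff_gradient(fn_tensor, arr)
    num = numeric_gradient(fn_scalar, arr, eps=eps)
    np.testing.assert_allclose(ana, num, rtol=rtol, atol=atol)
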