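import numpy as np
import pytest

from dranet import nn


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    flat, gf = x.ravel(), g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2.0 * eps)
    return g


def autodiff_grad(f, x: np.ndarray) -> np.ndarray:
    t = nn.Tensor(x.copy(), requires_grad=True)
    f(t).backward()
    return t.grad


def assert_grad_matches(f_tensor, f_scalar, x: np.ndarray, rtol: float = 1e-4,
                        atol: float = 5e-8):
    """Compare autodiff and finite-difference gradients: relative tolerance
    scaled by the gradient magnitude, with an absolute floor for the
    roundoff noise inherent in central differences."""
    ad = autodiff_grad(f_tensor, x)
    fd = finite_difference_grad(lambda a: f_scalar(a), x.copy())
    scale = max(np.abs(fd).max(), 1e-8)
    err = np.abs(ad - fd).max()
    assert err <= rtol * scale + atol, f"max abs err {err:.3g} vs scale {scale:.3g}"


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small on-disk synthetic dataset shared across I/O and training tests."""
    from dranet.synthetic import generate_dataset, preset

    root = tmp_path_factory.mktemp("tinyds")
    spec = preset("easy", size=(64, 64), seed=11)
    generate_dataset(spec, 8, 2, root)
    return root
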