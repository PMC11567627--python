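"""Shared fixtures: tiny phantom specs, RNGs, and a finite-difference oracle."""

from __future__ import annotations

import numpy as np
import pytest

from edtnet.autodiff import Tensor
from edtnet.phantoms import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def roi_spec() -> PhantomSpec:
    return PhantomSpec.roi(64)


@pytest.fixture(scope="session")
def tiny_samples(roi_spec):
    """Sixteen 64-px phantoms shared across read-only tests."""
    return generate_dataset(16, roi_spec, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def numeric_grad(fn, arrays, index, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar ``fn(*arrays)`` w.r.t. one input."""
    base = [np.asarray(a, dtype=np.float64).copy() for a in arrays]
    g = np.zeros_like(base[index])
    flat = base[index].reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(*base)
        flat[i] = orig - eps
        lo = fn(*base)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return g


def check_gradients(build, arrays, tol: float = 1e-6) -> None:
    """Compare autodiff gradients of ``build(*tensors).sum()`` against
    central differences for every input array."""
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    out = build(*tensors)
    out.sum().backward(free_graph=False)

    def scalar(*arrs):
        ts = [Tensor(a) for a in arrs]
        return float(build(*ts).sum().data)

    for i, t in enumerate(tensors):
        expected = numeric_grad(scalar, arrays, i)
        assert t.grad is not None, f"input {i} received no gradient"
        np.testing.assert_allclose(t.grad, expected, rtol=tol, atol=tol)
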