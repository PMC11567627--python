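"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run tape: each :class:`Tensor` wraps a float64
``numpy.ndarray`` and remembers the tensors it was computed from together
with a closure that propagates the upstream gradient. ``Tensor.backward()``
topologically sorts the tape and accumulates ``.grad`` arrays.

The primitive set is exactly what a windowed-attention encoder–decoder
needs: broadcasting arithmetic, batched matmul, reshape/transpose, softmax,
sigmoid, tanh, strided convolution and transposed convolution, and an
integer-gather used for relative-position bias lookup. Everything else
(layer norm, GELU, attention, losses) is composed from these, so a finite-
difference check of the primitives covers the whole model.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import math

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "softmax", "sigmoid", "tanh",
           "exp", "log", "gelu", "layer_norm", "conv2d", "conv_transpose2d",
           "bias_lookup"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float64 array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution is kept by reference (gradients are never
        # mutated in place); later contributions allocate a fresh sum
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- backward ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None,
                 free_graph: bool = True) -> None:
        """Accumulate gradients of ``self`` w.r.t. every graph leaf."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep for long loops
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if free_graph:
                    # interior node: release the tape eagerly so training
                    # loops do not wait on cyclic garbage collection
                    node._backward = None
                    node._parents = ()
                    node.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities ----------------------------------------

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = np.exp(x.data)
    out = Tensor(val, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * val)

    out._backward = backward
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    out._backward = backward
    return out


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = np.tanh(x.data)
    out = Tensor(val, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - val ** 2))

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = np.where(x.data >= 0,
                   1.0 / (1.0 + np.exp(-np.abs(x.data))),
                   np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    out = Tensor(val, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * val * (1.0 - val))

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    val = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(val, parents=(x,))

    def backward(g):
        if x.requires_grad:
            dot = (g * val).sum(axis=axis, keepdims=True)
            x._accumulate(val * (g - dot))

    out._backward = backward
    return out


def gelu(x: Tensor) -> Tensor:
    """Fused GELU (tanh approximation) with analytic gradient."""
    x = as_tensor(x)
    c = math.sqrt(2.0 / math.pi)
    u = c * (x.data + 0.044715 * x.data ** 3)
    t = np.tanh(u)
    out = Tensor(0.5 * x.data * (1.0 + t), parents=(x,))

    def backward(g):
        if x.requires_grad:
            du = c * (1.0 + 3 * 0.044715 * x.data ** 2)
            x._accumulate(g * (0.5 * (1.0 + t)
                               + 0.5 * x.data * (1.0 - t ** 2) * du))

    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Fused layer normalization over the last axis."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv
    out = Tensor(y * gamma.data + beta.data, parents=(x, gamma, beta))
    n = x.shape[-1]
    red = tuple(range(x.ndim - 1))

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=red))
        if gamma.requires_grad:
            gamma._accumulate((g * y).sum(axis=red))
        if x.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * y).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (gy - m1 - y * m2))

    out._backward = backward
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


# -- convolution primitives --------------------------------------------

def _conv_windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B,C,H,W) -> (B,C,Ho,Wo,k,k) strided view of sliding windows."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. ``x``: (B,Ci,H,W); ``w``: (Co,Ci,k,k)."""
    x, w = as_tensor(x), as_tensor(w)
    co, ci, k, _ = w.shape
    if x.shape[1] != ci:
        raise ValueError(f"conv2d channel mismatch: input {x.shape[1]}, weight {ci}")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    if (xp.shape[2] - k) % stride or (xp.shape[3] - k) % stride:
        raise ValueError(
            f"conv2d: spatial dims {xp.shape[2:]} not compatible with "
            f"kernel {k} stride {stride}")
    windows = _conv_windows(xp, k, stride)
    val = np.einsum("bcijkl,ockl->boij", windows, w.data, optimize=True)
    parents = (x, w) if b is None else (x, w, b)
    if b is not None:
        val = val + b.data[None, :, None, None]
    out = Tensor(val, parents=parents)
    ho, wo = val.shape[2], val.shape[3]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("bcijkl,boij->bockl", windows, g, optimize=True).sum(0)
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    patch = np.einsum("boij,oc->bcij", g, w.data[:, :, di, dj],
                                      optimize=True)
                    gxp[:, :, di:di + ho * stride:stride,
                        dj:dj + wo * stride:stride] += patch
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    out._backward = backward
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1) -> Tensor:
    """Transposed 2-D convolution. ``x``: (B,Ci,H,W); ``w``: (Ci,Co,k,k).

    Output spatial size is ``(H-1)*stride + k`` — the adjoint of
    :func:`conv2d` with the same kernel and stride and no padding.
    """
    x, w = as_tensor(x), as_tensor(w)
    ci, co, k, _ = w.shape
    if x.shape[1] != ci:
        raise ValueError(f"conv_transpose2d channel mismatch: input {x.shape[1]}, weight {ci}")
    bsz, _, h, ww_ = x.shape
    ho = (h - 1) * stride + k
    wo = (ww_ - 1) * stride + k
    val = np.zeros((bsz, co, ho, wo))
    for di in range(k):
        for dj in range(k):
            val[:, :, di:di + (h - 1) * stride + 1:stride,
                dj:dj + (ww_ - 1) * stride + 1:stride] += np.einsum(
                    "bcij,co->boij", x.data, w.data[:, :, di, dj], optimize=True)
    parents = (x, w) if b is None else (x, w, b)
    if b is not None:
        val = val + b.data[None, :, None, None]
    out = Tensor(val, parents=parents)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        windows = _conv_windows(g, k, stride)
        if w.requires_grad:
            gw = np.einsum("boijkl,bcij->cokl", windows, x.data, optimize=True)
            w._accumulate(gw)
        if x.requires_grad:
            gx = np.einsum("boijkl,cokl->bcij", windows, w.data, optimize=True)
            x._accumulate(gx)

    out._backward = backward
    return out


def bias_lookup(table: Tensor, idx: np.ndarray) -> Tensor:
    """Gather ``table[:, idx]``: (heads, T) × int (N,N) -> (heads, N, N).

    The backward pass scatter-adds into the table, so shared relative
    offsets accumulate gradient from every token pair that uses them.
    """
    table = as_tensor(table)
    idx = np.asarray(idx)
    if idx.min() < 0 or idx.max() >= table.shape[1]:
        raise IndexError("relative offset outside the bias table scope")
    out = Tensor(table.data[:, idx], parents=(table,))

    def backward(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            for h in range(table.shape[0]):
                np.add.at(gt[h], idx, g[h])
            table._accumulate(gt)

    out._backward = backward
    return out
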