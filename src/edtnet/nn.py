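"""Layers, parameter containers and the Adam optimizer.

Modules hold :class:`Parameter` leaves and child modules as attributes;
``named_parameters`` walks that tree, which gives deterministic ordering
(attribute insertion order) — important for reproducible training.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor leaf."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, state dicts, callable forward."""

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(unexpected)}")
        for name, p in own.items():
            if p.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.shape} vs {state[name].shape}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


def _normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    return rng.normal(0.0, std, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(_normal(rng, (in_dim, out_dim), 1.0 / math.sqrt(in_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, eps=self.eps)


class Conv2d(Module):
    """Strided 2-D convolution over (B, C, H, W) arrays."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, padding: int = 0, bias: bool = True):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_normal(rng, (out_ch, in_ch, kernel, kernel),
                                        1.0 / math.sqrt(fan_in)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Stride deconvolution over (B, C, H, W) arrays."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_normal(rng, (in_ch, out_ch, kernel, kernel),
                                        1.0 / math.sqrt(fan_in)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


def gelu(x: Tensor) -> Tensor:
    """GELU, tanh approximation (fused primitive)."""
    return ad.gelu(x)


class Mlp(Module):
    """Two-layer feed-forward block with GELU, expansion ratio 4 by default."""

    def __init__(self, dim: int, rng: np.random.Generator, expansion: int = 4):
        self.fc1 = Linear(dim, dim * expansion, rng)
        self.fc2 = Linear(dim * expansion, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class Adam:
    """Adam with the standard bias correction; no weight decay by default."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
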