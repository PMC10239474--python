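"""Parameterised layers on top of the autodiff tensor engine."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, conv3d, conv_down2, conv_up2, layernorm

__all__ = ["Module", "Linear", "LayerNorm", "Conv3d", "ConvDown2", "ConvUp2"]


class Module:
    """Container of named parameters and sub-modules."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _param(rng: np.random.Generator, shape, fan_in: int,
           gain: float = 1.0) -> Tensor:
    """Truncated-normal initialisation, std = gain / sqrt(fan_in), float32.

    The unit gain preserves activation variance through linear paths;
    layers feeding a ReLU pass gain sqrt(2) (He), and residual-branch
    output projections pass a small gain so an untrained network stays
    close to the identity scale.
    """
    std = gain / math.sqrt(fan_in)
    a = rng.standard_normal(shape)
    np.clip(a, -2.0, 2.0, out=a)
    return Tensor((a * std).astype(np.float32), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 gain: float = 1.0):
        self.weight = _param(rng, (n_in, n_out), n_in, gain)
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, n: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layernorm(x, self.gamma, self.beta, self.eps)


class Conv3d(Module):
    """Same-size 3D convolution with odd kernel, stride 1."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 k: int = 3, gain: float = 1.0):
        self.weight = _param(rng, (c_in, k, k, k, c_out), c_in * k ** 3, gain)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class ConvDown2(Module):
    """Downsampling convolution, kernel 2 / stride 2."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int):
        self.weight = _param(rng, (c_in, 2, 2, 2, c_out), c_in * 8)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_down2(x, self.weight, self.bias)


class ConvUp2(Module):
    """Upsampling transposed convolution, kernel 2 / stride 2."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int):
        self.weight = _param(rng, (c_in, 2, 2, 2, c_out), c_in)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_up2(x, self.weight, self.bias)
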