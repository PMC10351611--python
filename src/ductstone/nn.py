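"""Trainable layers and the RMSProp optimizer used by the detector.

Layers are thin parameter holders; the forward pass builds the autodiff
graph via the ops in :mod:`ductstone.autodiff`. Every layer registers its
parameters under a dotted name so checkpoints are flat name->array maps.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Conv2d", "Linear", "InstanceNorm2d", "RMSProp", "dropout"]


class Module:
    """Minimal parameter container with named-parameter traversal."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, Module] = {}

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value), requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.dtype)
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.shape}")
            p.data = arr.copy()


class Conv2d(Module):
    """Stride-1 same-padded convolution (odd kernel, optional dilation)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        zero_init: bool = False,
        bias: bool = True,
        bias_init: float = 0.0,
    ):
        super().__init__()
        self.dilation = dilation
        k = kernel_size
        fan_in = in_channels * k * k
        if zero_init or rng is None:
            w = np.zeros((out_channels, in_channels, k, k))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, k, k))
        self.weight = self.register("weight", w.astype(dtype))
        # convs feeding an instance-norm layer are bias-free (the norm would
        # cancel the shift, leaving a dead parameter)
        self.bias = (
            self.register("bias", np.full((out_channels,), bias_init, dtype=dtype))
            if bias
            else None
        )

    def __call__(self, x) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        zero_init: bool = False,
        bias_init: float = 0.0,
    ):
        super().__init__()
        if zero_init or rng is None:
            w = np.zeros((in_features, out_features))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.weight = self.register("weight", w.astype(dtype))
        self.bias = self.register(
            "bias", np.full((out_features,), bias_init, dtype=dtype)
        )

    def __call__(self, x) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias


class InstanceNorm2d(Module):
    """Per-image, per-channel standardization with a learnable affine."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = self.register("gamma", np.ones((1, channels, 1, 1), dtype=dtype))
        self.beta = self.register("beta", np.zeros((1, channels, 1, 1), dtype=dtype))

    def __call__(self, x) -> Tensor:
        mu = ad.reduce_mean(x, axis=(2, 3), keepdims=True)
        centred = x - mu
        var = ad.reduce_mean(centred * centred, axis=(2, 3), keepdims=True)
        inv = ad.power(var + self.eps, -0.5)
        return centred * inv * self.gamma + self.beta


def dropout(x, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.dtype) / (1.0 - p)
    return x * Tensor(mask)


class RMSProp:
    """RMSProp with decay rho and epsilon added outside the square root.

    update: s <- rho*s + (1-rho)*g^2 ; w <- w - lr * g / (sqrt(s) + eps)
    """

    def __init__(self, params, lr: float = 1e-4, rho: float = 0.9, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, s in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = p.grad
            s *= self.rho
            s += (1.0 - self.rho) * g * g
            p.data = p.data - self.lr * g / (np.sqrt(s) + self.eps)
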