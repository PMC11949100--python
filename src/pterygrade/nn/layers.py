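"""Trainable layers built on the autograd engine.

Initialisation is seeded: every layer draws its weights from the
``numpy.random.Generator`` passed at construction, so building the same
architecture twice from the same seed yields identical parameters.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, softmax


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal layer container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...],
               fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1, groups: int = 1,
                 bias: bool = True, zero_init: bool = False):
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        shape = (out_channels, in_channels // groups, k, k)
        w = np.zeros(shape) if zero_init else _he_normal(rng, shape, fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation,
                      groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(
            rng.standard_normal((in_features, out_features))
            * np.sqrt(1.0 / in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class GroupNorm(Module):
    """Group normalisation over channel groups of a (N, C, H, W) map.

    Batch-size independent, so small-batch CPU training stays stable.
    """

    def __init__(self, channels: int, groups: int | None = None,
                 eps: float = 1e-5):
        if groups is None:
            groups = 4 if channels % 4 == 0 else (2 if channels % 2 == 0 else 1)
        if channels % groups != 0:
            raise ValueError("channels must be divisible by groups")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(N, g, (C // g) * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        centred = xg - mu
        var = (centred * centred).mean(axis=2, keepdims=True)
        normed = (centred / (var + self.eps).sqrt()).reshape(N, C, H, W)
        return normed * self.gamma.reshape(1, C, 1, 1) \
            + self.beta.reshape(1, C, 1, 1)


class LayerNorm(Module):
    """Normalisation over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        normed = centred / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        N, T, D = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(N, T, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q = qkv.reshape(3, N * h, T, hd)
        # split via slicing-by-reshape: take rows 0,1,2 of the leading axis
        qs, ks, vs = (_take_first_axis(q, i) for i in range(3))
        attn = softmax((qs @ ks.transpose(0, 2, 1)) * (1.0 / np.sqrt(hd)),
                       axis=-1)
        out = (attn @ vs).reshape(N, h, T, hd).transpose(0, 2, 1, 3)
        return self.proj(out.reshape(N, T, D))


def _take_first_axis(x: Tensor, index: int) -> Tensor:
    """Select one slab along axis 0, with gradient scatter-back."""
    data = x.data[index]

    def grad_fn(g):
        out = np.zeros_like(x.data)
        out[index] = g
        return out

    return Tensor(data, parents=[(x, grad_fn)])


class TransformerBlock(Module):
    """Pre-norm transformer encoder block (attention + MLP, residual)."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: int,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).relu())


__all__ = [
    "Conv2d", "LayerNorm", "Linear", "Module", "MultiHeadSelfAttention",
    "Parameter", "TransformerBlock", "concat",
]
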