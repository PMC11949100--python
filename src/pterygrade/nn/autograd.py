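"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

This is the numerical substrate for the segmentation network: a
:class:`Tensor` wrapping an ``ndarray`` plus the operations the
encoder-decoder needs — broadcasting arithmetic, matmul, grouped/dilated
2D convolution (im2col forward, per-tap col2im backward), nearest
upsampling, reductions and the usual pointwise nonlinearities.  Gradients
are accumulated by topological-order backpropagation from a scalar loss.

It deliberately implements only what the package uses; it is not a
general deep-learning framework.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[tuple["Tensor", Callable[[Array], Array]]] = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self._parents = tuple(p for p in parents if p[0].requires_grad)
        self.requires_grad = requires_grad or bool(self._parents)

    # ---- graph -----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._parents:
                g = fn(node.grad)
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # ---- basic ops -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(self.data + other.data, parents=[
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(g, other.data.shape)),
        ])

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=[(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(self.data * other.data, parents=[
            (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
        ])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(self.data / other.data, parents=[
            (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
            (other, lambda g: _unbroadcast(
                -g * self.data / other.data**2, other.data.shape)),
        ])

    def __pow__(self, exponent: float):
        return Tensor(self.data**exponent, parents=[
            (self, lambda g: g * exponent * self.data ** (exponent - 1)),
        ])

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data

        def g_self(g: Array) -> Array:
            return _unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                self.data.shape)

        def g_other(g: Array) -> Array:
            return _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                other.data.shape)

        return Tensor(out, parents=[(self, g_self), (other, g_other)])

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape
        return Tensor(self.data.reshape(*shape),
                      parents=[(self, lambda g: g.reshape(orig))])

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(*axes),
                      parents=[(self, lambda g: g.transpose(*inv))])

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g: Array) -> Array:
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(out, parents=[(self, grad_fn)])

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def amax(self, axis, keepdims: bool = False) -> "Tensor":
        out = self.data.max(axis=axis, keepdims=keepdims)

        def grad_fn(g: Array) -> Array:
            outk = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == outk).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            gg = g if keepdims else np.expand_dims(g, axis)
            return mask * gg

        return Tensor(out, parents=[(self, grad_fn)])

    # ---- pointwise -------------------------------------------------------
    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor(out, parents=[(self, lambda g: g * out)])

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data),
                      parents=[(self, lambda g: g / self.data)])

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(self.data * mask, parents=[(self, lambda g: g * mask)])

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor(out, parents=[(self, lambda g: g * out * (1.0 - out))])

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)
        return Tensor(out, parents=[(self, lambda g: g * 0.5 / out)])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i: int):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        return lambda g: g[tuple(sl)]

    return Tensor(out, parents=[(t, make_fn(i)) for i, t in enumerate(tensors)])


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


# ---- convolution ----------------------------------------------------------

def _windows(xp: Array, kh: int, kw: int, stride: int, dilation: int) -> Array:
    """(..., Hp, Wp) -> (..., Hout, Wout, kh, kw) strided view."""
    kh_e = (kh - 1) * dilation + 1
    kw_e = (kw - 1) * dilation + 1
    v = sliding_window_view(xp, (kh_e, kw_e), axis=(-2, -1))
    return v[..., ::stride, ::stride, ::dilation, ::dilation]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """Grouped dilated 2D convolution.

    ``x``: (N, C, H, W); ``w``: (Cout, C/groups, kh, kw); ``b``: (Cout,).
    """
    N, C, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    G = groups
    if C != Cg * G or Cout % G != 0:
        raise ValueError(
            f"channel mismatch: input {C}, weight expects {Cg}x{G} groups")
    Og = Cout // G

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2:]
    v = _windows(xp, kh, kw, stride, dilation)  # (N, C, Ho, Wo, kh, kw) view
    Ho, Wo = v.shape[2], v.shape[3]

    # dense (groups == 1) and depthwise (groups == C) take copy-free einsum
    # paths; the general grouped case reshapes the window view
    if G == 1:
        out = np.einsum("nchwij,ocij->nohw", v, w.data, optimize=True)
    elif G == C and Og == 1:
        out = np.einsum("nchwij,cij->nchw", v, w.data[:, 0], optimize=True)
    else:
        vg = v.reshape(N, G, Cg, Ho, Wo, kh, kw)
        wg = w.data.reshape(G, Og, Cg, kh, kw)
        out = np.einsum("ngkhwij,gokij->ngohw", vg, wg,
                        optimize=True).reshape(N, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def g_x(g: Array) -> Array:
        if G == 1:
            dcol = np.einsum("nohw,ocij->nchwij", g, w.data, optimize=True)
        elif G == C and Og == 1:
            dcol = np.einsum("nchw,cij->nchwij", g, w.data[:, 0], optimize=True)
        else:
            gg = g.reshape(N, G, Og, Ho, Wo)
            wg = w.data.reshape(G, Og, Cg, kh, kw)
            dcol = np.einsum("ngohw,gokij->ngkhwij", gg, wg,
                             optimize=True).reshape(N, C, Ho, Wo, kh, kw)
        dxp = np.zeros((N, C, Hp, Wp))
        for i in range(kh):
            for j in range(kw):
                dxp[:, :,
                    i * dilation:i * dilation + stride * Ho:stride,
                    j * dilation:j * dilation + stride * Wo:stride] += \
                    dcol[:, :, :, :, i, j]
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        return dxp

    def g_w(g: Array) -> Array:
        if G == 1:
            return np.einsum("nohw,nchwij->ocij", g, v, optimize=True)
        if G == C and Og == 1:
            return np.einsum("nchw,nchwij->cij", g, v,
                             optimize=True)[:, None]
        gg = g.reshape(N, G, Og, Ho, Wo)
        vg = v.reshape(N, G, Cg, Ho, Wo, kh, kw)
        dw = np.einsum("ngohw,ngkhwij->gokij", gg, vg, optimize=True)
        return dw.reshape(Cout, Cg, kh, kw)

    parents: list[tuple[Tensor, Callable[[Array], Array]]] = [(x, g_x), (w, g_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=parents)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    N, C, H, W = x.data.shape

    def grad_fn(g: Array) -> Array:
        return g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))

    return Tensor(out, parents=[(x, grad_fn)])


def deform_depthwise_conv2d(x: Tensor, offsets: Tensor, w: Tensor, *,
                            dilation: int = 1, padding: int = 0) -> Tensor:
    """Depthwise convolution whose taps are displaced by learned offsets.

    ``x``: (N, C, H, W); ``w``: (C, 1, kh, kw); ``offsets``: (N, 2*kh*kw,
    H, W) giving per-position (dy, dx) for each tap, shared across
    channels.  Sampling is bilinear; gradients flow to the input, the
    kernel and the offsets.  Stride is fixed at 1 (shape-preserving, as
    used inside the attention module).
    """
    N, C, H, W = x.data.shape
    Cw, one, kh, kw = w.data.shape
    K = kh * kw
    if Cw != C or one != 1:
        raise ValueError("depthwise weight must have shape (C, 1, kh, kw)")
    if offsets.data.shape != (N, 2 * K, H, W):
        raise ValueError(
            f"offsets must have shape {(N, 2 * K, H, W)}, got {offsets.data.shape}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2:]
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    tap_y = (np.arange(kh).repeat(kw) * dilation).astype(np.float64)  # (K,)
    tap_x = (np.tile(np.arange(kw), kh) * dilation).astype(np.float64)

    off = offsets.data.reshape(N, K, 2, H, W)
    # absolute sampling positions in padded coordinates, (N, K, H, W)
    py = yy[None, None] + tap_y[None, :, None, None] + off[:, :, 0]
    px = xx[None, None] + tap_x[None, :, None, None] + off[:, :, 1]
    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    fy = py - y0
    fx = px - x0

    n_idx = np.arange(N)[:, None, None, None, None]
    c_idx = np.arange(C)[None, :, None, None, None]
    corners = []  # (cy, cx, wgt) per bilinear corner, all (N, K, H, W)
    for dy, wy in ((0, 1.0 - fy), (1, fy)):
        for dx_, wx in ((0, 1.0 - fx), (1, fx)):
            ry, rx = y0 + dy, x0 + dx_
            valid = (ry >= 0) & (ry < Hp) & (rx >= 0) & (rx < Wp)
            cy = np.clip(ry, 0, Hp - 1)
            cx = np.clip(rx, 0, Wp - 1)
            corners.append((cy, cx, wy * wx * valid, dy, dx_, wy, wx, valid))

    # channel-contiguous copy so each gathered index grabs a C-row at once
    xp_rows = np.ascontiguousarray(xp.transpose(0, 2, 3, 1)).reshape(-1, C)
    row_base = (np.arange(N) * Hp * Wp)[:, None, None, None]

    def _gather(cy: Array, cx: Array) -> Array:
        # (N, C, K, H, W) bilinear-corner values
        rows = xp_rows[row_base + cy * Wp + cx]  # (N, K, H, W, C)
        return np.moveaxis(rows, -1, 1)

    corner_vals = [_gather(cy, cx) for cy, cx, *_ in corners]
    sampled = np.zeros((N, C, K, H, W))
    for (cy, cx, wgt, *_), vals in zip(corners, corner_vals):
        sampled += wgt[:, None] * vals
    w_flat = w.data[:, 0].reshape(C, K)
    out = np.einsum("nckhw,ck->nchw", sampled, w_flat, optimize=True)

    def g_x(g: Array) -> Array:
        gk = g[:, :, None] * w_flat[None, :, :, None, None]  # (N, C, K, H, W)
        dxp = np.zeros(N * C * Hp * Wp)
        for cy, cx, wgt, *_ in corners:
            flat = ((n_idx * C + c_idx) * Hp + cy[:, None]) * Wp + cx[:, None]
            contrib = gk * wgt[:, None]
            dxp += np.bincount(np.broadcast_to(flat, contrib.shape).ravel(),
                               weights=contrib.ravel(), minlength=dxp.size)
        dxp = dxp.reshape(N, C, Hp, Wp)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        return dxp

    def g_w(g: Array) -> Array:
        dw = np.einsum("nchw,nckhw->ck", g, sampled, optimize=True)
        return dw.reshape(C, 1, kh, kw)

    def g_off(g: Array) -> Array:
        # accumulate d(out)/d(offset) through the bilinear weights
        doff = np.zeros((N, K, 2, H, W))
        for (cy, cx, wgt, dy, dx_, wy, wx, valid), vals in zip(corners,
                                                               corner_vals):
            contrib = np.einsum("nchw,nckhw,ck->nkhw", g, vals,
                                w_flat, optimize=True)
            sy = 1.0 if dy == 1 else -1.0
            sx = 1.0 if dx_ == 1 else -1.0
            doff[:, :, 0] += contrib * sy * wx * valid
            doff[:, :, 1] += contrib * wy * sx * valid
        return doff.reshape(N, 2 * K, H, W)

    return Tensor(out, parents=[(x, g_x), (w, g_w), (offsets, g_off)])
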