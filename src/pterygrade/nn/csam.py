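"""Channel-and-shape attention module (CSAM) for skip connections.

CSAM follows the two-stage CBAM layout: a channel gate followed by a
spatial ("shape") gate, combined multiplicatively with the skip feature
map F':

* channel branch — global average- and max-pooled channel descriptors are
  passed through a shared 1D convolution over the channel axis (the
  lightweight replacement for fully connected layers), summed, and
  squashed with a logistic sigmoid;
* spatial branch — a depthwise convolution, a depthwise dilated
  convolution and a 1x1 convolution form a large-kernel decomposition
  whose effective receptive field captures the lesion's wedge-like shape
  prior; both depthwise stages can be deformable, sampling their taps at
  learned offsets.

The output is ``sigmoid(Conv1x1(DWD(DW(F'))))  (x)  F'`` where F' has
already been channel-gated, so the module is shape-preserving and its
gate values lie in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, deform_depthwise_conv2d
from .layers import Conv2d, Module, Parameter


@dataclass(frozen=True)
class CSAMConfig:
    """Hyperparameters of the attention module (shared across stages)."""

    channel_attention_kernel: int = 3
    spatial_dw_kernel: int = 5
    spatial_dilated_kernel: int = 7
    spatial_dilation: int = 3
    deformable: bool = True
    dual_pool: bool = True  # avg+max channel descriptors vs avg only

    def __post_init__(self) -> None:
        for k in (self.channel_attention_kernel, self.spatial_dw_kernel,
                  self.spatial_dilated_kernel):
            if k <= 0 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and positive, got {k}")
        if self.spatial_dilation < 1:
            raise ValueError("dilation must be >= 1")


def conv1d_channels(d: Tensor, w: Tensor) -> Tensor:
    """Same-padded 1D convolution over the channel axis of (N, C)."""
    k = w.data.shape[0]
    pad = k // 2
    dp = np.pad(d.data, ((0, 0), (pad, pad)))
    win = sliding_window_view(dp, k, axis=1)  # (N, C, k)
    out = np.einsum("nck,k->nc", win, w.data)

    def g_d(g):
        gd = np.zeros_like(dp)
        for j in range(k):
            gd[:, j:j + d.data.shape[1]] += g * w.data[j]
        return gd[:, pad:pad + d.data.shape[1]] if pad else gd

    def g_w(g):
        return np.einsum("nck,nc->k", win, g)

    return Tensor(out, parents=[(d, g_d), (w, g_w)])


class CSAM(Module):
    """One CSAM instance, bound to a fixed channel count."""

    def __init__(self, channels: int, config: CSAMConfig,
                 rng: np.random.Generator):
        self.channels = channels
        self.config = config
        self.channel_kernel = Parameter(
            rng.standard_normal(config.channel_attention_kernel)
            * np.sqrt(1.0 / config.channel_attention_kernel))

        k1, k2 = config.spatial_dw_kernel, config.spatial_dilated_kernel
        dil = config.spatial_dilation
        self.dw = Conv2d(channels, channels, k1, rng, padding=k1 // 2,
                         groups=channels)
        self.dw_dilated = Conv2d(channels, channels, k2, rng,
                                 padding=(k2 // 2) * dil, dilation=dil,
                                 groups=channels)
        self.pointwise = Conv2d(channels, channels, 1, rng)
        if config.deformable:
            # zero-initialised offset heads: sampling starts on the
            # regular grid and deforms as training progresses
            self.offset1 = Conv2d(channels, 2 * k1 * k1, 3, rng, padding=1,
                                  zero_init=True)
            self.offset2 = Conv2d(channels, 2 * k2 * k2, 3, rng, padding=1,
                                  zero_init=True)

    def _channel_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))  # (N, C)
        gate = conv1d_channels(avg, self.channel_kernel)
        if self.config.dual_pool:
            gate = gate + conv1d_channels(x.amax(axis=(2, 3)),
                                          self.channel_kernel)
        N, C = gate.shape
        return gate.sigmoid().reshape(N, C, 1, 1)

    def _spatial_gate(self, f: Tensor) -> Tensor:
        cfg = self.config
        if cfg.deformable:
            k1, k2 = cfg.spatial_dw_kernel, cfg.spatial_dilated_kernel
            s = deform_depthwise_conv2d(f, self.offset1(f), self.dw.weight,
                                        padding=k1 // 2)
            if self.dw.bias is not None:
                s = s + self.dw.bias.reshape(1, self.channels, 1, 1)
            s = deform_depthwise_conv2d(s, self.offset2(s), self.dw_dilated.weight,
                                        dilation=cfg.spatial_dilation,
                                        padding=(k2 // 2) * cfg.spatial_dilation)
            if self.dw_dilated.bias is not None:
                s = s + self.dw_dilated.bias.reshape(1, self.channels, 1, 1)
        else:
            s = self.dw_dilated(self.dw(f))
        return self.pointwise(s).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"CSAM built for {self.channels} channels, got {x.shape[1]}")
        f_prime = x * self._channel_gate(x)
        return f_prime * self._spatial_gate(f_prime)


def csam_forward(feature_map, channels: int | None = None,
                 config: CSAMConfig = CSAMConfig(), seed: int = 0) -> Tensor:
    """Convenience one-shot CSAM application to a raw array or Tensor."""
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(feature_map)
    if channels is None:
        channels = x.shape[1]
    module = CSAM(channels, config, np.random.default_rng(seed))
    return module(x)
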