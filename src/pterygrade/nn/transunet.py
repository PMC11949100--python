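"""Hybrid CNN/transformer encoder-decoder segmentation network.

The encoder downsamples with strided convolutions (total stride 16) and
then runs transformer encoder blocks over the coarsest feature map, so
long-range context is aggregated by self-attention while the
convolutional stages keep local detail.  The decoder restores full
resolution by repeated 2x upsampling, fusing each encoder stage through a
skip connection; CSAM gates every skip feature map before fusion.

Two named configurations are provided: :func:`smoke_config` trains in
minutes on CPU-rendered phantoms, and :func:`paper_scale_config` records
the full-scale 512x512 layout (exercised here only for its forward-shape
contract, since training it requires clinical data and GPU budgets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, upsample_nearest2x
from .csam import CSAM, CSAMConfig
from .layers import Conv2d, GroupNorm, LayerNorm, Module, Parameter, TransformerBlock

TOTAL_STRIDE = 16


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters."""

    input_size_px: tuple[int, int] = (128, 128)
    n_classes: int = 4
    encoder_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    vit_dim: int = 64
    vit_depth: int = 2
    vit_heads: int = 4
    vit_mlp_ratio: int = 2
    use_csam: bool = True
    csam: CSAMConfig = field(default_factory=CSAMConfig)
    loss_weights: tuple[float, float] = (0.5, 0.5)  # (cross-entropy, dice)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if abs(sum(self.loss_weights) - 1.0) > 1e-12:
            raise ValueError("loss weights must sum to 1")
        H, W = self.input_size_px
        if H % TOTAL_STRIDE or W % TOTAL_STRIDE:
            raise ValueError(
                f"input size {self.input_size_px} must be a multiple of "
                f"{TOTAL_STRIDE} in each dimension")


def smoke_config(size: int = 128) -> NetConfig:
    """Small configuration for CPU smoke training on phantoms.

    The CSAM kernel sizes shrink with the image: a 3x3 depthwise plus a
    5x5 dilated (dilation 2) stage gives a receptive field proportionate
    to the reduced resolution.
    """
    return NetConfig(input_size_px=(size, size),
                     encoder_channels=(8, 16, 32, 64),
                     vit_dim=64, vit_depth=1, vit_heads=2,
                     csam=CSAMConfig(spatial_dw_kernel=3,
                                     spatial_dilated_kernel=5,
                                     spatial_dilation=2))


def paper_scale_config() -> NetConfig:
    """Full-scale layout: 512x512 input, wide encoder, deep transformer."""
    return NetConfig(input_size_px=(512, 512),
                     encoder_channels=(64, 128, 256, 512),
                     vit_dim=256, vit_depth=6, vit_heads=8, vit_mlp_ratio=4)


class _ConvStage(Module):
    def __init__(self, cin: int, cout: int, rng, stride: int = 2):
        self.conv = Conv2d(cin, cout, 3, rng, stride=stride, padding=1)
        self.norm1 = GroupNorm(cout)
        self.refine = Conv2d(cout, cout, 3, rng, padding=1)
        self.norm2 = GroupNorm(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm2(self.refine(
            self.norm1(self.conv(x)).relu())).relu()


class SegmentationModel(Module):
    """The full network; build with :func:`build_model`."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        self.config = config
        c1, c2, c3, c4 = config.encoder_channels
        H, W = config.input_size_px
        ht, wt = H // TOTAL_STRIDE, W // TOTAL_STRIDE

        self.stem = _ConvStage(3, c1, rng)       # /2
        self.enc2 = _ConvStage(c1, c2, rng)      # /4
        self.enc3 = _ConvStage(c2, c3, rng)      # /8
        self.enc4 = _ConvStage(c3, c4, rng)      # /16

        d = config.vit_dim
        self.proj_in = Conv2d(c4, d, 1, rng)
        self.pos_embed = Parameter(rng.standard_normal((1, ht * wt, d)) * 0.02)
        self.blocks = [TransformerBlock(d, config.vit_heads,
                                        config.vit_mlp_ratio, rng)
                       for _ in range(config.vit_depth)]
        self.vit_norm = LayerNorm(d)
        self.proj_out = Conv2d(d, c4, 1, rng)

        if config.use_csam:
            self.csam1 = CSAM(c1, config.csam, rng)
            self.csam2 = CSAM(c2, config.csam, rng)
            self.csam3 = CSAM(c3, config.csam, rng)

        self.dec3 = Conv2d(c4 + c3, c3, 3, rng, padding=1)
        self.dec3_norm = GroupNorm(c3)
        self.dec2 = Conv2d(c3 + c2, c2, 3, rng, padding=1)
        self.dec2_norm = GroupNorm(c2)
        self.dec1 = Conv2d(c2 + c1, c1, 3, rng, padding=1)
        self.dec1_norm = GroupNorm(c1)
        self.dec0 = Conv2d(c1, c1, 3, rng, padding=1)
        self.dec0_norm = GroupNorm(c1)
        self.head = Conv2d(c1, config.n_classes, 1, rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.data.ndim == 3:
            x = x.reshape(1, *x.data.shape)
        N, C, H, W = x.shape
        if (H, W) != tuple(self.config.input_size_px):
            raise ValueError(
                f"model built for input {self.config.input_size_px}, "
                f"got {(H, W)}")

        f1 = self.stem(x)
        f2 = self.enc2(f1)
        f3 = self.enc3(f2)
        f4 = self.enc4(f3)

        ht, wt = H // TOTAL_STRIDE, W // TOTAL_STRIDE
        d = self.config.vit_dim
        tokens = self.proj_in(f4).reshape(N, d, ht * wt).transpose(0, 2, 1)
        tokens = tokens + self.pos_embed
        for block in self.blocks:
            tokens = block(tokens)
        tokens = self.vit_norm(tokens)
        bottom = self.proj_out(
            tokens.transpose(0, 2, 1).reshape(N, d, ht, wt))

        s1, s2, s3 = f1, f2, f3
        if self.config.use_csam:
            s1, s2, s3 = self.csam1(f1), self.csam2(f2), self.csam3(f3)

        y = self.dec3_norm(
            self.dec3(concat([upsample_nearest2x(bottom), s3], axis=1))).relu()
        y = self.dec2_norm(
            self.dec2(concat([upsample_nearest2x(y), s2], axis=1))).relu()
        y = self.dec1_norm(
            self.dec1(concat([upsample_nearest2x(y), s1], axis=1))).relu()
        y = self.dec0_norm(self.dec0(upsample_nearest2x(y))).relu()
        return self.head(y)


def build_model(config: NetConfig, seed: int = 0) -> SegmentationModel:
    """Construct the network with seed-deterministic initialisation."""
    return SegmentationModel(config, np.random.default_rng(seed))
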