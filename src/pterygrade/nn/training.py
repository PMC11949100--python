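"""Smoke-scale training loop, prediction and checkpointing.

Training uses Adam with random horizontal/vertical flip augmentation; all
randomness is drawn from a single seed so runs are reproducible on fixed
hardware.  Checkpoints store every named parameter plus a config echo and
reload to bitwise-identical forward outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .csam import CSAMConfig
from .losses import combined_loss
from .transunet import NetConfig, SegmentationModel, build_model


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _augment(img: np.ndarray, mask: np.ndarray,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if rng.random() < 0.5:
        img, mask = img[:, :, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        img, mask = img[:, ::-1, :], mask[::-1, :]
    return np.ascontiguousarray(img), np.ascontiguousarray(mask)


def train_smoke(model: SegmentationModel,
                phantom_set: list[tuple[np.ndarray, np.ndarray]],
                epochs: int = 30, seed: int = 0, lr: float = 3e-3,
                batch_size: int = 4, augment: bool = True,
                ) -> tuple[list[float], SegmentationModel]:
    """Train in place; returns (per-epoch mean loss history, model)."""
    if len(phantom_set) == 0:
        raise ValueError("phantom_set must be non-empty")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    history: list[float] = []
    n = len(phantom_set)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            imgs, masks = [], []
            for i in idx:
                img, mask = phantom_set[i]
                if augment:
                    img, mask = _augment(img, mask, rng)
                imgs.append(img)
                masks.append(mask)
            x = Tensor(np.stack(imgs))
            y = np.stack(masks)
            opt.zero_grad()
            loss = combined_loss(model(x), y, model.config.loss_weights)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return history, model


def predict(model: SegmentationModel, image: np.ndarray) -> np.ndarray:
    """Argmax class mask (H, W) uint8 for one (3, H, W) image."""
    scores = model(Tensor(image[None] if image.ndim == 3 else image))
    return scores.data.argmax(axis=1)[0].astype(np.uint8)


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    cfg = dataclasses.asdict(model.config)
    arrays = {name: p.data for name, p in model.named_parameters()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> SegmentationModel:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["input_size_px"] = tuple(cfg["input_size_px"])
        cfg["encoder_channels"] = tuple(cfg["encoder_channels"])
        cfg["loss_weights"] = tuple(cfg["loss_weights"])
        cfg["csam"] = CSAMConfig(**cfg["csam"])
        model = build_model(NetConfig(**cfg))
        for name, p in model.named_parameters():
            p.data = data[name].copy()
    return model
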