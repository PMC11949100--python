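"""Combined cross-entropy / soft-Dice segmentation loss.

``loss = w_ce * CE + w_dice * (1 - soft Dice averaged over classes)``
with default weights (0.5, 0.5).  Cross-entropy is the mean pixelwise
negative log-probability of the true class; soft Dice uses the softmax
probabilities directly so the term is differentiable.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, log_softmax, softmax

_SMOOTH = 1e-6


def _one_hot(truth: np.ndarray, n_classes: int) -> np.ndarray:
    if truth.min() < 0 or truth.max() >= n_classes:
        raise ValueError(
            f"truth contains class codes outside [0, {n_classes - 1}]")
    eye = np.eye(n_classes)
    oh = eye[truth.astype(int)]           # (N, H, W, K)
    return np.moveaxis(oh, -1, 1)         # (N, K, H, W)


def combined_loss(predicted_class_scores, truth,
                  loss_weights: tuple[float, float] = (0.5, 0.5)):
    """Weighted sum of cross-entropy and Dice losses.

    ``predicted_class_scores``: logits of shape (N, K, H, W) or
    (K, H, W), Tensor or array.  ``truth``: integer mask of matching
    spatial shape.  Returns a scalar Tensor when the scores are a Tensor
    (so it can be backpropagated), otherwise a float.
    """
    is_tensor = isinstance(predicted_class_scores, Tensor)
    scores = predicted_class_scores if is_tensor else Tensor(predicted_class_scores)
    if scores.data.ndim == 3:
        scores = scores.reshape(1, *scores.data.shape)
    truth = np.asarray(truth)
    if truth.ndim == 2:
        truth = truth[None]
    N, K, H, W = scores.shape
    if truth.shape != (N, H, W):
        raise ValueError(
            f"truth shape {truth.shape} does not match scores {(N, H, W)}")
    target = _one_hot(truth, K)

    w_ce, w_dice = loss_weights
    logp = log_softmax(scores, axis=1)
    ce = -(logp * target).sum(axis=1).mean()

    probs = softmax(scores, axis=1)
    inter = (probs * target).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + Tensor(target.sum(axis=(0, 2, 3)))
    dice_per_class = (2.0 * inter + _SMOOTH) / (denom + _SMOOTH)
    dice_loss = 1.0 - dice_per_class.mean()

    total = ce * w_ce + dice_loss * w_dice
    return total if is_tensor else float(total.data)


def cross_entropy_term(predicted_class_scores, truth) -> float:
    """The cross-entropy component alone, as a float."""
    return combined_loss(np.asarray(
        predicted_class_scores.data if isinstance(predicted_class_scores, Tensor)
        else predicted_class_scores), truth, loss_weights=(1.0, 0.0))
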