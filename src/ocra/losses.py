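"""Margin classification loss, (optionally masked) reconstruction loss, and
their weighted sum.

The margin loss operates on cumulative class-capsule magnitudes so that a
target count of 2 (same class present twice) is attainable — per-step
magnitudes are bounded below 1 by the squash nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["LossConfig", "margin_loss", "reconstruction_loss", "total_loss"]


@dataclass
class LossConfig:
    """Loss weights.  ``masked`` enables the glimpse-coverage mask on the
    reconstruction term (cluttered task only)."""

    margin: float = 0.1
    lambda_absent: float = 0.5
    lambda_recon: float = 1.0
    masked: bool = False

    def __post_init__(self):
        if not (0.0 < self.margin < 1.0):
            raise ValueError("margin must be in (0, 1)")
        if self.lambda_absent < 0 or self.lambda_recon < 0:
            raise ValueError("loss weights must be nonnegative")


def margin_loss(scores: Tensor | np.ndarray, targets: np.ndarray,
                cfg: LossConfig) -> Tensor:
    """Hinge-squared class loss on cumulative magnitudes.

    ``targets`` holds per-class instance counts T_j (0, 1 or 2); entries of
    -1 mark unsupervised capsules (reasoning gist/temporary slots) that
    contribute nothing.  Per class:

        present (T_j >= 1):  max(0, (T_j - m) - s_j)²
        absent  (T_j == 0):  lambda_absent * max(0, s_j - m)²

    Batched inputs are summed over classes and averaged over the batch.
    """
    scores = as_tensor(scores)
    targets = np.asarray(targets, dtype=np.float64)
    if targets.shape != scores.shape:
        raise ValueError(
            f"targets shape {targets.shape} != scores shape {scores.shape}"
        )
    m = cfg.margin
    present_gate = np.maximum(0.0, np.minimum(targets, 1.0))
    absent_gate = np.maximum(0.0, 1.0 - np.maximum(targets, 0.0))
    absent_gate[targets < 0] = 0.0
    present = (Tensor(targets * present_gate - m * present_gate) - scores * present_gate).relu() ** 2
    absent = (scores * absent_gate - m * absent_gate).relu() ** 2
    per_class = Tensor(present_gate) * present + cfg.lambda_absent * absent
    per_image = per_class.sum(axis=-1)
    return per_image.mean() if per_image.ndim > 0 else per_image


def reconstruction_loss(canvas: Tensor | np.ndarray, image: Tensor | np.ndarray,
                        mask: Tensor | np.ndarray | None = None) -> Tensor:
    """Mean squared pixel error, optionally weighted by a coverage mask.

    The mask (entries in [0, 1], typically the episode-averaged read-glimpse
    coverage) is graded, not binarized; the mean is over all pixels.
    """
    canvas = as_tensor(canvas)
    image = as_tensor(image)
    if canvas.shape != image.shape:
        raise ValueError(f"canvas {canvas.shape} vs image {image.shape}")
    sq = (canvas - image) ** 2
    if mask is not None:
        mask = as_tensor(mask)
        if mask.shape[-2:] != canvas.shape[-2:]:
            raise ValueError("mask spatial shape does not match canvas")
        md = mask.data
        if md.min() < -1e-9 or md.max() > 1.0 + 1e-9:
            raise ValueError("mask entries must lie in [0, 1]")
        sq = mask * sq
    return sq.mean()


def total_loss(class_loss: Tensor | float, recon_loss: Tensor | float,
               cfg: LossConfig) -> Tensor:
    """``class_loss + lambda_recon * recon_loss``."""
    class_loss = as_tensor(class_loss)
    recon_loss = as_tensor(recon_loss)
    if not (np.all(np.isfinite(class_loss.data)) and np.all(np.isfinite(recon_loss.data))):
        raise ValueError("loss components must be finite")
    return class_loss + cfg.lambda_recon * recon_loss
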