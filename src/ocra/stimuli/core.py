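"""Shared dataset containers for generated stimuli."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StimulusSample:
    """One generated image with its labels and regeneration metadata."""

    image: np.ndarray                 # (H, W) float in [0, 1]
    labels: tuple                     # 2 class labels, or ("same",)/("different",)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        img = np.asarray(self.image)
        if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
            raise ValueError("image values must lie in [0, 1]")


@dataclass
class Dataset:
    images: np.ndarray                # (n, H, W) float32 in [0, 1]
    labels: list[tuple]
    meta: list[dict]
    task: str
    split: str = "train"

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> StimulusSample:
        return StimulusSample(self.images[i], self.labels[i], self.meta[i])
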