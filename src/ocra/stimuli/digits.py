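"""Two-digit composition benchmarks: overlapping pairs and cluttered scenes.

Both generators consume any digit source exposing ``images`` (n, 28, 28 in
[0, 1]), ``labels`` (n,) and ``split``; composition uses the pixelwise
maximum so intensities stay in [0, 1].
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .core import Dataset

DIGIT_SIZE = 28
MULTIMNIST_CANVAS = 36
CLUTTERED_CANVAS = 100
MAX_SHIFT = 4
N_CLUTTER = 6
CLUTTER_SIZE = 8


def _require_source(source, n_needed: int = 2):
    if source is None or len(source) < n_needed:
        raise ValueError(
            "digit source missing or exhausted; pass a real digit source or "
            "use ocra.stimuli.gen_fixture_glyphs() for a no-download source"
        )


def _ink_bbox(img: np.ndarray, thresh: float = 0.0) -> tuple[int, int, int, int]:
    """Tight (row0, col0, row1, col1) box around pixels above ``thresh``
    (half-open on the high side)."""
    rows = np.any(img > thresh, axis=1)
    cols = np.any(img > thresh, axis=0)
    r = np.where(rows)[0]
    c = np.where(cols)[0]
    if len(r) == 0:
        return (0, 0, 0, 0)
    return (int(r[0]), int(c[0]), int(r[-1]) + 1, int(c[-1]) + 1)


def bbox_overlap(box_a, box_b, metric: str = "iou") -> float:
    """Overlap between two (r0, c0, r1, c1) boxes.

    ``metric="iou"``: intersection / union; ``metric="min"``: intersection /
    area of the smaller box.
    """
    r0 = max(box_a[0], box_b[0])
    c0 = max(box_a[1], box_b[1])
    r1 = min(box_a[2], box_b[2])
    c1 = min(box_a[3], box_b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    area_a = (box_a[2] - box_a[0]) * (box_a[3] - box_a[1])
    area_b = (box_b[2] - box_b[0]) * (box_b[3] - box_b[1])
    if metric == "iou":
        denom = area_a + area_b - inter
    elif metric == "min":
        denom = min(area_a, area_b)
    else:
        raise ValueError(f"unknown overlap metric {metric!r}")
    return inter / denom if denom > 0 else 0.0


def _place(canvas: np.ndarray, digit: np.ndarray, top: int, left: int):
    h, w = digit.shape
    region = canvas[top:top + h, left:left + w]
    np.maximum(region, digit, out=region)


def gen_multimnist(digit_source, n: int, seed: int = 0,
                   split: str | None = None) -> Dataset:
    """Overlay two different-class digits on a 36 × 36 canvas.

    Each digit is independently shifted from the centered position by
    integer offsets uniform in [-4, 4] per axis; the composite is the
    pixelwise maximum.
    """
    _require_source(digit_source)
    rng = np.random.default_rng([seed, 1])
    imgs = np.asarray(digit_source.images)
    labels = np.asarray(digit_source.labels)
    split = split or getattr(digit_source, "split", "train")
    base = (MULTIMNIST_CANVAS - DIGIT_SIZE) // 2  # = MAX_SHIFT

    images = np.zeros((n, MULTIMNIST_CANVAS, MULTIMNIST_CANVAS), dtype=np.float32)
    out_labels: list[tuple] = []
    meta: list[dict] = []
    for i in range(n):
        a = int(rng.integers(len(imgs)))
        b = int(rng.integers(len(imgs)))
        while labels[b] == labels[a]:
            b = int(rng.integers(len(imgs)))
        offsets = rng.integers(-MAX_SHIFT, MAX_SHIFT + 1, size=(2, 2))
        boxes = []
        for src, (dy, dx) in zip((a, b), offsets):
            top, left = base + int(dy), base + int(dx)
            _place(images[i], imgs[src], top, left)
            r0, c0, r1, c1 = _ink_bbox(imgs[src])
            boxes.append((r0 + top, c0 + left, r1 + top, c1 + left))
        out_labels.append(tuple(sorted((int(labels[a]), int(labels[b])))))
        meta.append({
            "source_ids": [a, b],
            "offsets": offsets.tolist(),
            "ink_boxes": boxes,
            "seed": seed,
            "index": i,
        })
    return Dataset(images=images, labels=out_labels, meta=meta,
                   task="multimnist", split=split)


def mean_bbox_overlap(digit_source, n: int = 10_000, seed: int = 0,
                      metric: str = "iou") -> float:
    """Mean pairwise ink-box overlap of generated two-digit samples, in %.

    Streams sample generation (no image storage) so large ``n`` is cheap.
    """
    _require_source(digit_source)
    rng = np.random.default_rng([seed, 1])
    imgs = np.asarray(digit_source.images)
    labels = np.asarray(digit_source.labels)
    base = (MULTIMNIST_CANVAS - DIGIT_SIZE) // 2
    # precompute per-digit ink boxes once
    boxes = np.array([_ink_bbox(img) for img in imgs])

    total = 0.0
    for _ in range(n):
        a = int(rng.integers(len(imgs)))
        b = int(rng.integers(len(imgs)))
        while labels[b] == labels[a]:
            b = int(rng.integers(len(imgs)))
        offsets = rng.integers(-MAX_SHIFT, MAX_SHIFT + 1, size=(2, 2))
        placed = []
        for src, (dy, dx) in zip((a, b), offsets):
            r0, c0, r1, c1 = boxes[src]
            placed.append((r0 + base + dy, c0 + base + dx,
                           r1 + base + dy, c1 + base + dx))
        total += bbox_overlap(placed[0], placed[1], metric=metric)
    return 100.0 * total / n


def gen_cluttered(digit_source, n: int, seed: int = 0,
                  split: str | None = None, n_clutter: int = N_CLUTTER) -> Dataset:
    """Two digits plus ``n_clutter`` 8 × 8 digit-fragment pieces at random
    positions on a 100 × 100 canvas.  Digit classes may repeat."""
    _require_source(digit_source, n_needed=3)
    rng = np.random.default_rng([seed, 2])
    imgs = np.asarray(digit_source.images)
    labels = np.asarray(digit_source.labels)
    split = split or getattr(digit_source, "split", "train")
    lim = CLUTTERED_CANVAS - DIGIT_SIZE
    clim = CLUTTERED_CANVAS - CLUTTER_SIZE
    crop_lim = DIGIT_SIZE - CLUTTER_SIZE

    images = np.zeros((n, CLUTTERED_CANVAS, CLUTTERED_CANVAS), dtype=np.float32)
    out_labels: list[tuple] = []
    meta: list[dict] = []
    for i in range(n):
        digit_ids = rng.integers(len(imgs), size=2)
        positions = rng.integers(0, lim + 1, size=(2, 2))
        for src, (top, left) in zip(digit_ids, positions):
            _place(images[i], imgs[int(src)], int(top), int(left))
        clutter_meta = []
        for _ in range(n_clutter):
            src = int(rng.integers(len(imgs)))
            while src in digit_ids:  # clutter never cut from this canvas's digits
                src = int(rng.integers(len(imgs)))
            cy, cx = rng.integers(0, crop_lim + 1, size=2)
            patch = imgs[src][cy:cy + CLUTTER_SIZE, cx:cx + CLUTTER_SIZE]
            top, left = rng.integers(0, clim + 1, size=2)
            _place(images[i], patch, int(top), int(left))
            clutter_meta.append({"source_id": src, "crop": [int(cy), int(cx)],
                                 "pos": [int(top), int(left)]})
        out_labels.append(tuple(sorted(int(labels[d]) for d in digit_ids)))
        meta.append({
            "source_ids": digit_ids.tolist(),
            "positions": positions.tolist(),
            "clutter": clutter_meta,
            "seed": seed,
            "index": i,
        })
    return Dataset(images=images, labels=out_labels, meta=meta,
                   task="cluttered", split=split)


def load_mnist_idx(directory: str | Path, split: str = "train"):
    """Load IDX-format handwritten-digit files if the user has them locally.

    Expects ``{train|t10k}-images-idx3-ubyte`` and the matching labels file
    (uncompressed) inside ``directory``.
    """
    directory = Path(directory)
    prefix = "train" if split == "train" else "t10k"
    img_path = directory / f"{prefix}-images-idx3-ubyte"
    lbl_path = directory / f"{prefix}-labels-idx1-ubyte"
    if not img_path.exists() or not lbl_path.exists():
        raise FileNotFoundError(
            f"IDX files not found under {directory}; use gen_fixture_glyphs() "
            "for a procedural no-download digit source"
        )
    with open(img_path, "rb") as f:
        magic, n, rows, cols = struct.unpack(">IIII", f.read(16))
        if magic != 2051:
            raise ValueError("bad magic number in images file")
        images = np.frombuffer(f.read(), dtype=np.uint8).reshape(n, rows, cols)
    with open(lbl_path, "rb") as f:
        magic, n_l = struct.unpack(">II", f.read(8))
        if magic != 2049:
            raise ValueError("bad magic number in labels file")
        labels = np.frombuffer(f.read(), dtype=np.uint8)

    class _Source:
        pass

    src = _Source()
    src.images = images.astype(np.float32) / 255.0
    src.labels = labels.astype(np.int64)
    src.split = split
    src.__class__.__len__ = lambda self: len(self.images)
    return src
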