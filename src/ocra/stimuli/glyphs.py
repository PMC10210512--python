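"""Procedural fixture glyphs: a no-download stand-in for handwritten digits.

Ten stroke-based glyph classes are rendered on 28 × 28 canvases with
per-sample jitter (control-point noise, rotation, blur), exposing the same
``images``/``labels``/``split`` interface as a real digit source so every
digit-benchmark code path runs without external data.  Glyph strokes span
roughly 24 pixels, comparable to the ink extent of size-normalized
handwritten digits.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

SIZE = 28

def _circle(cx, cy, r, n=40):
    t = np.linspace(0, 2 * np.pi, n, endpoint=True)
    return np.stack([cx + r * np.cos(t), cy + r * np.sin(t)], axis=1)


def _arc(cx, cy, r, a0, a1, n=24):
    t = np.linspace(a0, a1, n)
    return np.stack([cx + r * np.cos(t), cy + r * np.sin(t)], axis=1)


# control polylines in [0, 1]² (x right, y down), one list of strokes per class
def _templates() -> list[list[np.ndarray]]:
    return [
        # 0: ellipse
        [_circle(0.5, 0.5, 0.42)],
        # 1: vertical stroke with serif
        [np.array([[0.35, 0.25], [0.55, 0.05], [0.55, 0.95]])],
        # 2: top arc, diagonal, base bar
        [_arc(0.5, 0.3, 0.28, np.pi, 2 * np.pi),
         np.array([[0.78, 0.3], [0.15, 0.95], [0.85, 0.95]])],
        # 3: two right-facing arcs
        [_arc(0.45, 0.28, 0.25, -0.6 * np.pi, 0.5 * np.pi),
         _arc(0.45, 0.74, 0.25, -0.5 * np.pi, 0.6 * np.pi)],
        # 4: open angle plus vertical
        [np.array([[0.6, 0.05], [0.15, 0.6], [0.85, 0.6]]),
         np.array([[0.62, 0.3], [0.62, 0.95]])],
        # 5: flag: top bar, left drop, bottom bowl
        [np.array([[0.8, 0.08], [0.25, 0.08], [0.22, 0.5]]),
         _arc(0.47, 0.68, 0.26, -0.5 * np.pi, 0.7 * np.pi)],
        # 6: tail into lower loop
        [np.array([[0.65, 0.05], [0.3, 0.5]]),
         _circle(0.45, 0.7, 0.24)],
        # 7: top bar and long diagonal
        [np.array([[0.15, 0.1], [0.85, 0.1], [0.35, 0.95]])],
        # 8: stacked loops
        [_circle(0.5, 0.28, 0.2), _circle(0.5, 0.72, 0.24)],
        # 9: loop with straight tail
        [_circle(0.5, 0.32, 0.23),
         np.array([[0.73, 0.32], [0.68, 0.95]])],
    ]


_TEMPLATES = _templates()


def render_glyph(cls: int, rng: np.random.Generator) -> np.ndarray:
    """Render one jittered 28 × 28 glyph of class ``cls``, values in [0, 1]."""
    canvas = np.zeros((SIZE, SIZE))
    angle = rng.normal(0.0, 0.08)
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    scale = 24.0 * rng.uniform(0.92, 1.05)
    shift = rng.normal(0.0, 0.6, size=2)
    for stroke in _TEMPLATES[cls]:
        pts = stroke + rng.normal(0.0, 0.015, size=stroke.shape)
        pts = (pts - 0.5) @ rot.T * scale + (SIZE - 1) / 2.0 + shift
        pts = np.clip(pts, 0, SIZE - 1)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc, val = line_aa(int(round(y0)), int(round(x0)),
                                  int(round(y1)), int(round(x1)))
            canvas[rr, cc] = np.maximum(canvas[rr, cc], val)
    canvas = gaussian_filter(canvas, sigma=rng.uniform(0.5, 0.8))
    peak = canvas.max()
    if peak > 0:
        canvas = canvas / peak
    return canvas


class FixtureGlyphs:
    """Digit-source protocol backed by procedural glyphs.

    ``split`` only changes the seed stream, so train/test draws never
    collide for distinct splits under the same base seed.
    """

    def __init__(self, n: int, seed: int = 0, split: str = "train"):
        self.split = split
        self.n = n
        base = np.random.default_rng([seed, hash(split) % (2**31)])
        self.labels = np.arange(n) % 10
        base.shuffle(self.labels)
        self.images = np.empty((n, SIZE, SIZE), dtype=np.float32)
        for i in range(n):
            rng = np.random.default_rng([seed, hash(split) % (2**31), i])
            self.images[i] = render_glyph(int(self.labels[i]), rng)

    def __len__(self):
        return self.n


def gen_fixture_glyphs(n: int, seed: int = 0, split: str = "train") -> FixtureGlyphs:
    return FixtureGlyphs(n, seed=seed, split=split)
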