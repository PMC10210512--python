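"""Same–different stimuli: two procedurally generated shapes on a 64 × 64
canvas; "same" images repeat one shape at two positions, "different" images
draw two independent shapes from the same family.

The nine training families and four held-out (OOD) families are named,
parameterized stand-ins — closed radial contours, polygons, stars and open
stroke figures — chosen to span a range of curvature statistics.  They are
not a pixel-level replication of any external stimulus code.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from skimage.draw import polygon_perimeter, polygon, line

from .core import Dataset

CANVAS = 64

IN_DISTRIBUTION_FAMILIES = (
    "blob_smooth",
    "blob_spiky",
    "polygon_irregular",
    "polygon_convex",
    "star",
    "rounded_square",
    "wobble_ellipse",
    "bumpy_circle",
    "two_lobe",
)

OOD_FAMILIES = (
    "arrow",
    "polyline_open",
    "squashed_ellipse",
    "filled_blob",
)


# ----------------------------------------------------------------- contours
def _radial_contour(rng, k_range, radius_sigma, smooth: bool) -> np.ndarray:
    k = int(rng.integers(*k_range))
    theta = np.sort(rng.uniform(0, 2 * np.pi, k))
    radii = np.exp(rng.normal(0.0, radius_sigma, k))
    if smooth:
        t = np.append(theta, theta[0] + 2 * np.pi)
        r = np.append(radii, radii[0])
        spline = CubicSpline(t, r, bc_type="periodic")
        theta_dense = np.linspace(theta[0], theta[0] + 2 * np.pi, 100)
        radii, theta = spline(theta_dense), theta_dense
    radii = np.clip(radii, 0.2, 3.0)
    return np.stack([radii * np.cos(theta), radii * np.sin(theta)], axis=1)


def _periodic_radius(rng, fn, n=100) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    radii = np.clip(fn(theta), 0.2, 3.0)
    return np.stack([radii * np.cos(theta), radii * np.sin(theta)], axis=1)


def _contour_points(family: str, rng: np.random.Generator):
    """Return (points (k, 2), closed?, filled?) in shape-local coordinates."""
    if family == "blob_smooth":
        return _radial_contour(rng, (8, 13), 0.25, True), True, False
    if family == "blob_spiky":
        return _radial_contour(rng, (7, 11), 0.55, False), True, False
    if family == "polygon_irregular":
        return _radial_contour(rng, (5, 9), 0.35, False), True, False
    if family == "polygon_convex":
        pts = rng.normal(0, 1, (10, 2))
        from scipy.spatial import ConvexHull
        hull = ConvexHull(pts)
        return pts[hull.vertices], True, False
    if family == "star":
        k = int(rng.integers(4, 7))
        theta = np.linspace(0, 2 * np.pi, 2 * k, endpoint=False)
        theta = theta + rng.uniform(0, 2 * np.pi)
        radii = np.where(np.arange(2 * k) % 2 == 0, 1.0,
                         rng.uniform(0.35, 0.55))
        return np.stack([radii * np.cos(theta), radii * np.sin(theta)],
                        axis=1), True, False
    if family == "rounded_square":
        p = rng.uniform(3.0, 5.0)
        wob = rng.uniform(0.0, 0.12)
        ph = rng.uniform(0, 2 * np.pi)
        return _periodic_radius(
            rng, lambda t: (np.abs(np.cos(t))**p + np.abs(np.sin(t))**p)
            ** (-1.0 / p) * (1 + wob * np.sin(3 * t + ph))), True, False
    if family == "wobble_ellipse":
        a, b = 1.0, rng.uniform(0.45, 0.75)
        w = rng.uniform(0.03, 0.1)
        m = int(rng.integers(4, 8))
        ph = rng.uniform(0, 2 * np.pi)
        return _periodic_radius(
            rng, lambda t: a * b / np.sqrt((b * np.cos(t))**2 + (a * np.sin(t))**2)
            * (1 + w * np.sin(m * t + ph))), True, False
    if family == "bumpy_circle":
        m = int(rng.integers(5, 10))
        amp = rng.uniform(0.12, 0.3)
        ph = rng.uniform(0, 2 * np.pi)
        return _periodic_radius(rng, lambda t: 1 + amp * np.sin(m * t + ph)), True, False
    if family == "two_lobe":
        amp = rng.uniform(0.3, 0.6)
        ph = rng.uniform(0, 2 * np.pi)
        sq = rng.uniform(0.6, 1.0)
        return _periodic_radius(
            rng, lambda t: sq * (1 + amp * np.abs(np.cos(t / 2 * 2 + ph / 2)))
        ), True, False
    if family == "squashed_ellipse":
        b = rng.uniform(0.12, 0.3)
        return _periodic_radius(
            rng, lambda t: b / np.sqrt((b * np.cos(t))**2 + np.sin(t)**2)), True, False
    if family == "filled_blob":
        return _radial_contour(rng, (7, 12), 0.3, True), True, True
    if family == "arrow":
        length = 1.0
        head = rng.uniform(0.3, 0.5)
        spread = rng.uniform(0.35, 0.7)
        pts = np.array([
            [-length, 0.0], [length, 0.0],                     # shaft
            [length - head, spread * head], [length, 0.0],
            [length - head, -spread * head], [length, 0.0],
        ])
        return pts, False, False
    if family == "polyline_open":
        k = int(rng.integers(4, 7))
        return rng.uniform(-1, 1, (k, 2)), False, False
    raise ValueError(f"unknown shape family {family!r}")


def render_shape(family: str, rng: np.random.Generator,
                 target_size: float | None = None) -> np.ndarray:
    """Rasterize one shape as a 1-valued stroke mask cropped to its ink."""
    pts, closed, filled = _contour_points(family, rng)
    angle = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    pts = pts @ rot.T
    if target_size is None:
        target_size = rng.uniform(13, 24)
    span = pts.max(axis=0) - pts.min(axis=0)
    pts = (pts - pts.min(axis=0)) / max(span.max(), 1e-9) * (target_size - 1)
    dim = int(np.ceil(pts.max())) + 2
    canvas = np.zeros((dim, dim))
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, dim - 1)
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, dim - 1)
    if filled:
        rr, cc = polygon(rows, cols, shape=canvas.shape)
        canvas[rr, cc] = 1.0
    elif closed:
        rr, cc = polygon_perimeter(rows, cols, shape=canvas.shape, clip=True)
        canvas[rr, cc] = 1.0
    else:
        for i in range(len(rows) - 1):
            rr, cc = line(rows[i], cols[i], rows[i + 1], cols[i + 1])
            canvas[rr, cc] = 1.0
    # crop to ink
    r = np.where(canvas.any(axis=1))[0]
    c = np.where(canvas.any(axis=0))[0]
    return canvas[r[0]:r[-1] + 1, c[0]:c[-1] + 1]


def _boxes_disjoint(a, b, margin: int = 1) -> bool:
    return (a[2] + margin <= b[0] or b[2] + margin <= a[0]
            or a[3] + margin <= b[1] or b[3] + margin <= a[1])


def _place_pair(rng, mask_a, mask_b, tries: int = 60):
    """Two non-overlapping top-left positions, or None if placement failed."""
    for _ in range(tries):
        pa = rng.integers(0, CANVAS - mask_a.shape[0] + 1), \
             rng.integers(0, CANVAS - mask_a.shape[1] + 1)
        pb = rng.integers(0, CANVAS - mask_b.shape[0] + 1), \
             rng.integers(0, CANVAS - mask_b.shape[1] + 1)
        box_a = (pa[0], pa[1], pa[0] + mask_a.shape[0], pa[1] + mask_a.shape[1])
        box_b = (pb[0], pb[1], pb[0] + mask_b.shape[0], pb[1] + mask_b.shape[1])
        if _boxes_disjoint(box_a, box_b):
            return (int(pa[0]), int(pa[1])), (int(pb[0]), int(pb[1]))
    return None


def gen_svrt1(n: int, seed: int = 0, families: tuple[str, ...] | None = None,
              ood: bool = False, split: str = "train") -> Dataset:
    """Generate ``n`` class-balanced same–different images (even indices are
    "same").  ``ood=True`` switches to the held-out shape families."""
    if families is None:
        families = OOD_FAMILIES if ood else IN_DISTRIBUTION_FAMILIES
    if not families:
        raise ValueError("families must be nonempty")
    images = np.zeros((n, CANVAS, CANVAS), dtype=np.float32)
    labels: list[tuple] = []
    meta: list[dict] = []
    for i in range(n):
        label = "same" if i % 2 == 0 else "different"
        rng = np.random.default_rng([seed, 3, i])
        family = families[int(rng.integers(len(families)))]
        for attempt in range(20):
            mask_a = render_shape(family, rng)
            mask_b = mask_a if label == "same" else render_shape(family, rng)
            placed = _place_pair(rng, mask_a, mask_b)
            if placed is not None:
                break
        else:
            raise RuntimeError("could not place shapes after bounded retries")
        (ra, ca), (rb, cb) = placed
        images[i, ra:ra + mask_a.shape[0], ca:ca + mask_a.shape[1]] = \
            np.maximum(images[i, ra:ra + mask_a.shape[0], ca:ca + mask_a.shape[1]],
                       mask_a)
        images[i, rb:rb + mask_b.shape[0], cb:cb + mask_b.shape[1]] = \
            np.maximum(images[i, rb:rb + mask_b.shape[0], cb:cb + mask_b.shape[1]],
                       mask_b)
        labels.append((label,))
        meta.append({"family": family, "positions": [[ra, ca], [rb, cb]],
                     "ood": ood, "seed": seed, "index": i})
    return Dataset(images=images, labels=labels, meta=meta,
                   task="reasoning", split=split)
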