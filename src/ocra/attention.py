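"""Differentiable Gaussian-filterbank read/write attention.

A glimpse is taken by laying an N × N grid of Gaussian filters over the
image.  Four pose parameters control the grid — center column ``g_x``,
center row ``g_y``, inter-filter stride ``delta`` and filter variance
``sigma2`` — so a single window trades coverage against resolution
("zoom lens"): a wide grid samples the whole image coarsely, a narrow grid
samples a small region at near-pixel resolution.

Coordinate conventions (used everywhere in this package): images are
row-major with the origin at the top-left; filter-center algebra is
1-based, i.e. pixel centers sit at coordinates 1..W (columns) and 1..H
(rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "AttentionPose",
    "FilterGrid",
    "pose_from_raw",
    "pose_from_hidden",
    "build_filters",
    "read",
    "write",
    "retroject_coverage",
]

#: floor applied to each filter row's normalizer, so rows whose Gaussian mass
#: falls entirely off-image normalize to ~0 instead of 0/0.
EPS_NORM = 1e-8


@dataclass
class AttentionPose:
    """Glimpse-grid pose; leading axes (if any) are batch axes.

    ``center_x``/``center_y`` are in 1-based image column/row units,
    ``stride`` is the pixel distance between adjacent grid filters and
    ``variance`` the Gaussian variance in pixels².
    """

    center_x: Tensor
    center_y: Tensor
    stride: Tensor
    variance: Tensor

    def numpy(self) -> dict[str, np.ndarray]:
        return {
            "center_x": self.center_x.data,
            "center_y": self.center_y.data,
            "stride": self.stride.data,
            "variance": self.variance.data,
        }


@dataclass
class FilterGrid:
    """Row/column filter matrices; last two axes are (N, H) and (N, W)."""

    row_filters: Tensor
    col_filters: Tensor
    grid_size: int
    image_height: int
    image_width: int


def pose_from_raw(raw: Tensor | np.ndarray, grid_size: int,
                  image_shape: tuple[int, int]) -> AttentionPose:
    """Map 4 unconstrained values (last axis) to a valid pose.

    The mapping guarantees ``stride >= 0`` and ``variance > 0`` for any
    finite input and is differentiable everywhere:

    * ``center = (dim + 1) * (raw + 1) / 2``  (1-based axis)
    * ``stride = exp(raw) * (max(H, W) - 1) / (N - 1)``
    * ``variance = exp(raw)``

    so an all-zero raw vector yields a grid centered on the image whose
    filters span the full image with unit variance.
    """
    raw = as_tensor(raw)
    if not np.all(np.isfinite(raw.data)):
        raise ValueError("non-finite raw pose values")
    if raw.shape[-1] != 4:
        raise ValueError(f"raw pose must have 4 components, got {raw.shape[-1]}")
    H, W = image_shape
    span = (max(H, W) - 1) / (grid_size - 1) if grid_size > 1 else 1.0
    center_x = (raw[..., 0] + 1.0) * ((W + 1) / 2.0)
    center_y = (raw[..., 1] + 1.0) * ((H + 1) / 2.0)
    stride = raw[..., 2].exp() * span
    variance = raw[..., 3].exp()
    return AttentionPose(center_x, center_y, stride, variance)


def pose_from_hidden(hidden: Tensor, projection, grid_size: int,
                     image_shape: tuple[int, int]) -> AttentionPose:
    """Project a decoder state through a linear map onto a valid pose."""
    if not np.all(np.isfinite(as_tensor(hidden).data)):
        raise ValueError("non-finite hidden state passed to pose projection")
    return pose_from_raw(projection(as_tensor(hidden)), grid_size, image_shape)


def _axis_filters(center: Tensor, stride: Tensor, variance: Tensor,
                  grid_size: int, dim: int) -> Tensor:
    # mu_i = center + (i - N/2 - 0.5) * stride, i = 1..N (1-based)
    offsets = np.arange(1, grid_size + 1) - grid_size / 2.0 - 0.5
    mu = center.reshape(center.shape + (1,)) + Tensor(offsets) * stride.reshape(
        stride.shape + (1,)
    )                                                        # (..., N)
    pos = np.arange(1, dim + 1, dtype=np.float64)            # pixel centers
    diff = mu.reshape(mu.shape + (1,)) - Tensor(pos)         # (..., N, dim)
    var = variance.reshape(variance.shape + (1, 1))
    f = (-(diff * diff) / (2.0 * var)).exp()
    norm = f.sum(axis=-1, keepdims=True) + EPS_NORM
    return f / norm


def build_filters(pose: AttentionPose, grid_size: int,
                  image_shape: tuple[int, int]) -> FilterGrid:
    """Build L1-normalized row/column Gaussian filter matrices for a pose."""
    H, W = image_shape
    if grid_size < 1 or H < 1 or W < 1:
        raise ValueError("grid size and image dimensions must be >= 1")
    return FilterGrid(
        row_filters=_axis_filters(pose.center_y, pose.stride, pose.variance,
                                  grid_size, H),
        col_filters=_axis_filters(pose.center_x, pose.stride, pose.variance,
                                  grid_size, W),
        grid_size=grid_size,
        image_height=H,
        image_width=W,
    )


def read(image: Tensor | np.ndarray, grid: FilterGrid) -> Tensor:
    """Extract an N × N glimpse: ``F_y · image · F_xᵀ`` (linear in the image)."""
    image = as_tensor(image)
    if image.shape[-2:] != (grid.image_height, grid.image_width):
        raise ValueError(
            f"image shape {image.shape[-2:]} does not match grid "
            f"({grid.image_height}, {grid.image_width})"
        )
    fx_t = grid.col_filters.transpose(
        *range(grid.col_filters.ndim - 2), -1, -2
    )
    return grid.row_filters @ image @ fx_t


def write(patch: Tensor | np.ndarray, grid: FilterGrid) -> Tensor:
    """Project an N × N patch back to image size: ``F_yᵀ · patch · F_x``.

    This is the adjoint of :func:`read` under the same grid:
    ``<write(p), x> == <p, read(x)>``.
    """
    patch = as_tensor(patch)
    if patch.shape[-2:] != (grid.grid_size, grid.grid_size):
        raise ValueError(
            f"patch shape {patch.shape[-2:]} does not match grid size "
            f"{grid.grid_size}"
        )
    fy_t = grid.row_filters.transpose(
        *range(grid.row_filters.ndim - 2), -1, -2
    )
    return fy_t @ patch @ grid.col_filters


def retroject_coverage(grid: FilterGrid) -> Tensor:
    """Image-space coverage of a grid: write an all-ones patch, rescale to 1.

    Used by the masked reconstruction objective to restrict the loss to
    glimpsed areas.
    """
    shape = grid.row_filters.shape[:-2] + (grid.grid_size, grid.grid_size)
    cov = write(Tensor(np.ones(shape)), grid)
    peak = cov.max(axis=(-2, -1), keepdims=True) + EPS_NORM
    return cov / peak
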