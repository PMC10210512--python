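"""Capsule layer with routing-by-agreement and max–min coupling normalization.

Primary ("part") capsules each predict every class ("whole") capsule via a
learned linear transform.  Predictions are combined with coupling
coefficients, squashed, and the dot-product agreement between the squashed
class capsule and each prediction feeds back into the couplings.  The
couplings are renormalized every iteration with a max–min rule onto
[lb, ub] — not a softmax — so that the best-matching class saturates at
``ub`` and the worst at ``lb``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, where
from .nn import Module, _glorot

__all__ = [
    "CouplingState",
    "ClassCapsules",
    "maxmin_normalize",
    "squash",
    "CapsuleRouter",
    "route",
    "mask_most_active",
]

LB_DEFAULT = 0.01
UB_DEFAULT = 1.0
_DEGENERATE_TOL = 1e-12
_SQUASH_EPS = 1e-12


@dataclass
class CouplingState:
    """Raw agreement accumulators and their normalized couplings."""

    raw: Tensor          # (..., n_primary, n_class)
    normalized: Tensor   # entries in [lb, ub]
    lb: float = LB_DEFAULT
    ub: float = UB_DEFAULT


@dataclass
class ClassCapsules:
    pre_squash: Tensor   # (..., n_class, class_dim)
    post_squash: Tensor
    magnitudes: Tensor   # (..., n_class), each in [0, 1)


def maxmin_normalize(raw: Tensor | np.ndarray, lb: float = LB_DEFAULT,
                     ub: float = UB_DEFAULT, axis: int = -1) -> Tensor:
    """Affinely map each slice along ``axis`` onto [lb, ub].

    ``out = lb + (ub - lb) * (raw - min) / (max - min)``.  A degenerate
    slice (max − min below 1e−12) maps to the constant ``(lb + ub) / 2``.
    """
    raw = as_tensor(raw)
    if not np.all(np.isfinite(raw.data)):
        raise ValueError("non-finite values passed to max-min normalization")
    lo = raw.min(axis=axis, keepdims=True)
    hi = raw.max(axis=axis, keepdims=True)
    span = hi - lo
    degenerate = span.data < _DEGENERATE_TOL
    scaled = lb + (ub - lb) * (raw - lo) / (span + Tensor(degenerate * 1.0))
    midpoint = Tensor(np.full(raw.shape, (lb + ub) / 2.0))
    return where(np.broadcast_to(degenerate, raw.shape), midpoint, scaled)


def squash(v: Tensor | np.ndarray, axis: int = -1) -> Tensor:
    """Shrink ``v`` along its own direction to magnitude ``|v|²/(1+|v|²) < 1``."""
    v = as_tensor(v)
    n2 = (v * v).sum(axis=axis, keepdims=True)
    scale = n2 / (1.0 + n2) / (n2 + _SQUASH_EPS).sqrt()
    return v * scale


class CapsuleRouter(Module):
    """Bias-free prediction transforms plus the routing loop."""

    def __init__(self, n_primary: int, primary_dim: int, n_class: int,
                 class_dim: int, rng: np.random.Generator,
                 iterations: int = 3, lb: float = LB_DEFAULT,
                 ub: float = UB_DEFAULT):
        self.n_primary = n_primary
        self.primary_dim = primary_dim
        self.n_class = n_class
        self.class_dim = class_dim
        self.iterations = iterations
        self.lb, self.ub = lb, ub
        # (n_primary, n_class, primary_dim, class_dim); no bias terms
        self.transforms = Tensor(
            _glorot(rng, primary_dim, class_dim,
                    (n_primary, n_class, primary_dim, class_dim)),
            requires_grad=True,
        )

    def __call__(self, primary: Tensor) -> tuple[ClassCapsules, CouplingState]:
        return route(primary, self.transforms, iterations=self.iterations,
                     lb=self.lb, ub=self.ub)


def route(primary: Tensor | np.ndarray, transforms: Tensor | np.ndarray,
          iterations: int = 3, lb: float = LB_DEFAULT,
          ub: float = UB_DEFAULT) -> tuple[ClassCapsules, CouplingState]:
    """Route primary capsules to class capsules by agreement.

    ``primary``: (..., n_primary, primary_dim);
    ``transforms``: (n_primary, n_class, primary_dim, class_dim).

    Per iteration: couplings c = maxmin(raw) per primary capsule across the
    class axis; v_j = Σ_i c_ij p̂_j|i; d_j = squash(v_j);
    raw_ij += d_j · p̂_j|i.  Raw accumulators start at zero, so the first
    normalization is degenerate and routing starts uniform at (lb+ub)/2.
    Returned couplings are the normalization of the final raw state.
    """
    primary = as_tensor(primary)
    transforms = as_tensor(transforms)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n_primary, n_class, p_dim, c_dim = transforms.shape
    if primary.shape[-2:] != (n_primary, p_dim):
        raise ValueError(
            f"primary capsules {primary.shape[-2:]} incompatible with "
            f"transforms ({n_primary}, {p_dim})"
        )
    batch = primary.shape[:-2]

    # predictions p̂_j|i = W_ij p_i  -> (..., n_primary, n_class, class_dim)
    p = primary.reshape(batch + (n_primary, 1, 1, p_dim))
    predictions = (p @ transforms).reshape(batch + (n_primary, n_class, c_dim))

    raw = Tensor(np.zeros(batch + (n_primary, n_class)))
    capsules = None
    for _ in range(iterations):
        c = maxmin_normalize(raw, lb, ub, axis=-1)
        v = (c.reshape(c.shape + (1,)) * predictions).sum(axis=-3)
        d = squash(v, axis=-1)
        capsules = ClassCapsules(
            pre_squash=v,
            post_squash=d,
            magnitudes=((d * d).sum(axis=-1) + _SQUASH_EPS).sqrt(),
        )
        agreement = (d.reshape(batch + (1, n_class, c_dim)) * predictions).sum(axis=-1)
        raw = raw + agreement
    coupling = CouplingState(
        raw=raw, normalized=maxmin_normalize(raw, lb, ub, axis=-1), lb=lb, ub=ub
    )
    return capsules, coupling


def mask_most_active(capsules: ClassCapsules) -> Tensor:
    """Concatenate class capsules, zeroing all but the strongest one.

    Output length is ``n_class * class_dim``; ties break to the lowest
    capsule index (``argmax`` convention).  The selection itself is
    non-differentiable, but gradients flow through the retained block.
    """
    d = capsules.post_squash
    mags = capsules.magnitudes.data
    winner = np.argmax(mags, axis=-1)
    onehot = np.zeros(d.shape[:-1] + (1,))
    np.put_along_axis(
        onehot[..., 0], winner[..., None], 1.0, axis=-1
    )
    masked = d * Tensor(onehot)
    return masked.reshape(d.shape[:-2] + (d.shape[-2] * d.shape[-1],))
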