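"""The object-centric recurrent attention model.

Each timestep: a pose is decoded from the previous decoder state; a glimpse
is read through the Gaussian filterbank; a small CNN and the encoder LSTM
produce a feature state; primary capsules are read out linearly and routed
to class capsules; capsule magnitudes accumulate into the class scores; the
masked (most-active) capsule vector drives the decoder LSTM, which emits a
write patch and write pose that increment the reconstruction canvas.

Variants ablate the glimpse mechanism (full image every step), recurrence
(single feedforward pass) or the capsule layers (two fully connected
layers with a linear class readout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .nn import Module, Linear, LSTMCell, conv2d, maxpool2d
from . import attention
from .routing import CapsuleRouter, mask_most_active

__all__ = [
    "TASK_SHAPES",
    "ModelConfig",
    "StepTrace",
    "Episode",
    "OCRA",
    "build_variant",
    "predict_digits",
    "predict_same_different",
]

TASK_SHAPES = {
    "multimnist": (36, 36),
    "cluttered": (100, 100),
    "reasoning": (64, 64),
}

_DEFAULT_TIMESTEPS = {"multimnist": 3, "cluttered": 5, "reasoning": 10}


@dataclass
class ModelConfig:
    task: str = "multimnist"
    timesteps: int | None = None
    glimpse_size: int = 18
    patch_size: int = 18
    conv_channels: tuple[int, int] = (32, 32)
    conv_kernels: tuple[int, int] = (5, 3)
    recurrent_size: int = 512
    n_primary: int = 40
    primary_dim: int = 8
    n_class: int | None = None
    class_dim: int = 16
    routing_iterations: int = 3
    feedback: bool | None = None
    variant: str = "full"
    response_idx: tuple[int, int] = (0, 1)  # (same, different) capsules

    def __post_init__(self):
        if self.task not in TASK_SHAPES:
            raise ValueError(f"unknown task {self.task!r}")
        if self.variant not in {"full", "recurrent_noglimpse", "feedforward",
                                "no_capsules"}:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_class is None:
            self.n_class = 4 if self.task == "reasoning" else 10
        if self.feedback is None:
            self.feedback = self.task == "reasoning"
        if self.timesteps is None:
            self.timesteps = _DEFAULT_TIMESTEPS[self.task]
        if self.variant == "feedforward":
            if self.feedback:
                raise ValueError("feedforward variant has no recurrence to feed back to")
            self.timesteps = 1
        if self.task == "reasoning" and self.n_class < 2:
            raise ValueError("reasoning task needs at least the 2 response capsules")

    @property
    def image_shape(self) -> tuple[int, int]:
        return TASK_SHAPES[self.task]

    @property
    def uses_glimpse(self) -> bool:
        return self.variant in {"full", "no_capsules"}

    @property
    def uses_recurrence(self) -> bool:
        return self.variant != "feedforward"

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("conv_channels", "conv_kernels", "response_idx"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("conv_channels", "conv_kernels", "response_idx"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class StepTrace:
    """Detached per-timestep record (NumPy arrays, no graph)."""

    read_pose: dict[str, np.ndarray] | None
    glimpse: np.ndarray | None
    conv_features: np.ndarray
    class_magnitudes: np.ndarray
    most_active: np.ndarray
    write_pose: dict[str, np.ndarray] | None
    canvas_increment: np.ndarray


@dataclass
class Episode:
    traces: list[StepTrace]
    cumulative_scores: Tensor      # (B, n_class); graph-attached
    canvas: Tensor                 # (B, H, W); graph-attached
    coverage: Tensor | None        # episode-averaged read coverage, or None
    config: ModelConfig = field(repr=False, default=None)


def _conv_out_features(shape: tuple[int, int], channels: tuple[int, int]) -> int:
    h, w = shape
    h, w = h // 2, w // 2
    h, w = h // 2, w // 2
    return channels[1] * h * w


class OCRA(Module):
    """Assembled model for one :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        H, W = c.image_shape
        k1, k2 = c.conv_kernels
        ch1, ch2 = c.conv_channels

        self.conv1_w = Tensor(
            np.random.default_rng(rng.integers(2**32)).normal(
                0, np.sqrt(2.0 / (k1 * k1)), (1, ch1, k1, k1)),
            requires_grad=True)
        self.conv1_b = Tensor(np.zeros(ch1), requires_grad=True)
        self.conv2_w = Tensor(
            np.random.default_rng(rng.integers(2**32)).normal(
                0, np.sqrt(2.0 / (k2 * k2 * ch1)), (ch1, ch2, k2, k2)),
            requires_grad=True)
        self.conv2_b = Tensor(np.zeros(ch2), requires_grad=True)

        cnn_input = (c.glimpse_size, c.glimpse_size) if c.uses_glimpse else (H, W)
        self.conv_features = _conv_out_features(cnn_input, c.conv_channels)

        R = c.recurrent_size
        enc_in = self.conv_features + (R if c.feedback else 0)
        dec_in = c.n_class * c.class_dim if c.variant != "no_capsules" else 160
        if c.uses_recurrence:
            self.encoder = LSTMCell(enc_in, R, np.random.default_rng(rng.integers(2**32)))
            self.decoder = LSTMCell(dec_in, R, np.random.default_rng(rng.integers(2**32)))
        else:
            self.encoder = Linear(enc_in, R, np.random.default_rng(rng.integers(2**32)))
            self.decoder = Linear(dec_in, R, np.random.default_rng(rng.integers(2**32)))

        if c.variant == "no_capsules":
            r = np.random.default_rng(rng.integers(2**32))
            self.fc1 = Linear(R, 320, r)
            self.fc2 = Linear(320, 160, r)
            self.class_readout = Linear(160, c.n_class, r)
        else:
            self.primary_readout = Linear(
                R, c.n_primary * c.primary_dim,
                np.random.default_rng(rng.integers(2**32)))
            self.router = CapsuleRouter(
                c.n_primary, c.primary_dim, c.n_class, c.class_dim,
                np.random.default_rng(rng.integers(2**32)),
                iterations=c.routing_iterations)

        if c.uses_glimpse:
            r = np.random.default_rng(rng.integers(2**32))
            self.read_pose_proj = Linear(R, 4, r)
            self.write_pose_proj = Linear(R, 4, r)
            self.write_patch_proj = Linear(R, c.patch_size * c.patch_size, r)
        else:
            self.write_full_proj = Linear(
                R, H * W, np.random.default_rng(rng.integers(2**32)))

    # ------------------------------------------------------------------ pieces
    def _cnn(self, x: Tensor) -> Tensor:
        """(B, h, w) -> flattened conv features (B, F)."""
        B = x.shape[0]
        h = x.reshape(B, 1, x.shape[1], x.shape[2])
        h = conv2d(h, self.conv1_w, self.conv1_b, self.config.conv_kernels[0] // 2).relu()
        h = maxpool2d(h)
        h = conv2d(h, self.conv2_w, self.conv2_b, self.config.conv_kernels[1] // 2).relu()
        h = maxpool2d(h)
        return h.reshape(B, self.conv_features)

    def _classify(self, h_enc: Tensor):
        """Return (step scores, decoder input, magnitudes array)."""
        c = self.config
        if c.variant == "no_capsules":
            f = self.fc2(self.fc1(h_enc).relu()).relu()
            scores = self.class_readout(f)
            return scores, f, scores.data
        B = h_enc.shape[0]
        primary = self.primary_readout(h_enc).reshape(B, c.n_primary, c.primary_dim)
        capsules, _ = self.router(primary)
        if c.variant == "feedforward":
            dec_in = capsules.post_squash.reshape(B, c.n_class * c.class_dim)
        else:
            dec_in = mask_most_active(capsules)
        return capsules.magnitudes, dec_in, capsules.magnitudes.data

    # ----------------------------------------------------------------- episode
    def run_episode(self, image: Tensor | np.ndarray) -> Episode:
        c = self.config
        H, W = c.image_shape
        x = as_tensor(image)
        squeeze = x.ndim == 2
        if squeeze:
            x = x.reshape(1, H, W)
        if x.shape[-2:] != (H, W):
            raise ValueError(
                f"image shape {x.shape[-2:]} does not match task canvas ({H}, {W})")
        B = x.shape[0]
        R = c.recurrent_size

        zeros_R = Tensor(np.zeros((B, R)))
        h_enc, c_enc = zeros_R, Tensor(np.zeros((B, R)))
        h_dec, c_dec = Tensor(np.zeros((B, R))), Tensor(np.zeros((B, R)))
        canvas = Tensor(np.zeros((B, H, W)))
        cum_scores = Tensor(np.zeros((B, c.n_class)))
        coverage_sum = None
        traces: list[StepTrace] = []

        for t in range(c.timesteps):
            read_pose = glimpse = None
            if c.uses_glimpse:
                read_pose = attention.pose_from_hidden(
                    h_dec, self.read_pose_proj, c.glimpse_size, (H, W))
                grid = attention.build_filters(read_pose, c.glimpse_size, (H, W))
                glimpse = attention.read(x, grid)
                cov = attention.retroject_coverage(grid)
                coverage_sum = cov if coverage_sum is None else coverage_sum + cov
                cnn_in = glimpse
            else:
                cnn_in = x
            feats = self._cnn(cnn_in)

            enc_in = concat([feats, h_dec], axis=-1) if c.feedback else feats
            if c.uses_recurrence:
                h_enc, c_enc = self.encoder(enc_in, h_enc, c_enc)
            else:
                h_enc = self.encoder(enc_in).relu()
            if not np.all(np.isfinite(h_enc.data)):
                raise FloatingPointError(f"non-finite encoder state at timestep {t}")

            step_scores, dec_in, mags = self._classify(h_enc)
            cum_scores = cum_scores + step_scores

            if c.uses_recurrence:
                h_dec, c_dec = self.decoder(dec_in, h_dec, c_dec)
            else:
                h_dec = self.decoder(dec_in).relu()
            if not np.all(np.isfinite(h_dec.data)):
                raise FloatingPointError(f"non-finite decoder state at timestep {t}")

            write_pose = None
            if c.uses_glimpse:
                patch = self.write_patch_proj(h_dec).reshape(B, c.patch_size, c.patch_size)
                write_pose = attention.pose_from_hidden(
                    h_dec, self.write_pose_proj, c.patch_size, (H, W))
                wgrid = attention.build_filters(write_pose, c.patch_size, (H, W))
                increment = attention.write(patch, wgrid)
            else:
                increment = self.write_full_proj(h_dec).reshape(B, H, W)
            canvas = canvas + increment

            traces.append(StepTrace(
                read_pose=read_pose.numpy() if read_pose is not None else None,
                glimpse=glimpse.data.copy() if glimpse is not None else None,
                conv_features=feats.data.copy(),
                class_magnitudes=np.asarray(mags).copy(),
                most_active=np.argmax(mags, axis=-1),
                write_pose=write_pose.numpy() if write_pose is not None else None,
                canvas_increment=increment.data.copy(),
            ))

        coverage = None
        if coverage_sum is not None:
            coverage = coverage_sum * (1.0 / c.timesteps)
        if squeeze:
            cum_scores = cum_scores.reshape(c.n_class)
            canvas = canvas.reshape(H, W)
            if coverage is not None:
                coverage = coverage.reshape(H, W)
        return Episode(traces=traces, cumulative_scores=cum_scores,
                       canvas=canvas, coverage=coverage, config=c)


def build_variant(config: ModelConfig, seed: int = 0) -> OCRA:
    """Construct the model for ``config.variant`` (validates combinations)."""
    if config.variant == "feedforward" and config.feedback:
        raise ValueError("feedforward variant cannot use decoder feedback")
    return OCRA(config, seed=seed)


def predict_digits(cumulative_scores: np.ndarray) -> np.ndarray:
    """Top-2 multiset decision from cumulative class scores.

    The winning class is predicted twice iff its score exceeds every other
    class's score by more than 1 (each episode step contributes < 1 per
    instance); ties break to the lowest index.  Returns sorted label pairs,
    shape (..., 2).
    """
    s = np.asarray(cumulative_scores, dtype=np.float64)
    squeeze = s.ndim == 1
    s = np.atleast_2d(s)
    first = np.argmax(s, axis=-1)
    masked = s.copy()
    np.put_along_axis(masked, first[:, None], -np.inf, axis=-1)
    runner = np.argmax(masked, axis=-1)
    runner_score = np.take_along_axis(masked, runner[:, None], axis=-1)[:, 0]
    first_score = np.take_along_axis(s, first[:, None], axis=-1)[:, 0]
    second = np.where(first_score - 1.0 > runner_score, first, runner)
    out = np.sort(np.stack([first, second], axis=-1), axis=-1)
    return out[0] if squeeze else out


def predict_same_different(cumulative_scores: np.ndarray,
                           response_idx: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Argmax over the two response capsules; ties resolve to "different"."""
    s = np.asarray(cumulative_scores, dtype=np.float64)
    i_same, i_diff = response_idx
    squeeze = s.ndim == 1
    s = np.atleast_2d(s)
    labels = np.where(s[:, i_same] > s[:, i_diff], "same", "different")
    return labels[0] if squeeze else labels
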