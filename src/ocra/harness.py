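"""Training/evaluation harness: run configuration, parameter accounting,
the Adam training loop with CSV logging and checkpointing, image-level
evaluation, multi-seed aggregation and glimpse-trajectory visualization."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .autodiff import no_grad
from .losses import LossConfig, margin_loss, reconstruction_loss, total_loss
from .model import (
    ModelConfig,
    OCRA,
    build_variant,
    predict_digits,
    predict_same_different,
)
from .nn import Adam
from .stimuli import Dataset, gen_fixture_glyphs, gen_multimnist, gen_cluttered, gen_svrt1

__all__ = [
    "RunConfig",
    "EvalReport",
    "count_parameters",
    "targets_for_labels",
    "train",
    "evaluate",
    "visualize",
    "mean_sem",
    "save_checkpoint",
    "load_checkpoint",
    "build_dataset",
]


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    lr: float = 1e-3
    batch_size: int = 128
    epochs: int = 10
    seed: int = 0
    n_train: int = 2000
    n_val: int = 200
    digit_source: str = "fixtures"   # "fixtures" or a path to IDX files
    data_dir: str | None = None      # load pre-generated data instead
    out_dir: str = "runs/run"
    patience: int | None = None      # early stopping on validation accuracy

    def to_yaml(self, path: str | Path):
        d = asdict(self)
        d["model"] = self.model.to_dict()
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        d["model"] = ModelConfig.from_dict(d.get("model", {}))
        d["loss"] = LossConfig(**d.get("loss", {}))
        return cls(**d)


@dataclass
class EvalReport:
    image_level_accuracy: float
    n_images: int
    per_class_correct: dict
    n_runs: int = 1
    mean: float | None = None
    sem: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float, indent=2)


def count_parameters(config: ModelConfig) -> int:
    """Exact count of trainable scalars in the assembled model."""
    return build_variant(config, seed=0).n_parameters()


def targets_for_labels(labels: list[tuple], config: ModelConfig) -> np.ndarray:
    """Per-class instance-count targets for the margin loss.

    Recognition: counts of each class among the 2 labels.  Reasoning: the
    correct response capsule gets 1, the other response capsule 0, and the
    non-response (gist/temporary) capsules are marked unsupervised (-1).
    """
    n = len(labels)
    if config.task == "reasoning":
        t = np.full((n, config.n_class), -1.0)
        i_same, i_diff = config.response_idx
        for k, lab in enumerate(labels):
            same = lab[0] == "same"
            t[k, i_same] = 1.0 if same else 0.0
            t[k, i_diff] = 0.0 if same else 1.0
        return t
    t = np.zeros((n, config.n_class))
    for k, lab in enumerate(labels):
        for cls in lab:
            t[k, int(cls)] += 1.0
    return t


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def build_dataset(run: RunConfig, split: str, n: int) -> Dataset:
    """Generate (or load) the dataset a run config describes."""
    if run.data_dir is not None:
        from .stimuli import load_dataset
        return load_dataset(run.data_dir, split=split)
    task = run.model.task
    seed = run.seed + (0 if split == "train" else 10_000)
    if task == "reasoning":
        return gen_svrt1(n, seed=seed, split=split)
    if run.digit_source == "fixtures":
        source = gen_fixture_glyphs(max(200, n // 2), seed=run.seed, split=split)
    else:
        from .stimuli import load_mnist_idx
        source = load_mnist_idx(run.digit_source,
                                split="train" if split == "train" else "test")
    gen = gen_multimnist if task == "multimnist" else gen_cluttered
    return gen(source, n, seed=seed, split=split)


def save_checkpoint(model: OCRA, path: str | Path, seed: int,
                    extra: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {"config": model.config.to_dict(), "seed": seed}
    sidecar.update(extra or {})
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> OCRA:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    config = ModelConfig.from_dict(sidecar["config"])
    model = build_variant(config, seed=sidecar.get("seed", 0))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def _epoch_pass(model: OCRA, data: Dataset, run: RunConfig,
                optimizer: Adam | None, rng: np.random.Generator) -> dict:
    cfg = run.model
    totals = {"class_loss": 0.0, "recon_loss": 0.0, "total": 0.0}
    n_batches = 0
    for idx in _batches(len(data), run.batch_size, rng):
        images = np.asarray(data.images[idx], dtype=np.float64)
        targets = targets_for_labels([data.labels[i] for i in idx], cfg)
        episode = model.run_episode(images)
        cls = margin_loss(episode.cumulative_scores, targets, run.loss)
        mask = episode.coverage if (run.loss.masked and episode.coverage is not None) else None
        rec = reconstruction_loss(episode.canvas, images, mask)
        loss = total_loss(cls, rec, run.loss)
        if not np.isfinite(loss.data):
            raise RuntimeError("non-finite loss; halting")
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        totals["class_loss"] += float(cls.data)
        totals["recon_loss"] += float(rec.data)
        totals["total"] += float(loss.data)
        n_batches += 1
    return {k: v / max(n_batches, 1) for k, v in totals.items()}


def train(run: RunConfig, train_data: Dataset | None = None,
          val_data: Dataset | None = None, verbose: bool = False):
    """Adam-optimize the combined loss; returns (model, history).

    Writes a per-epoch CSV log and a checkpoint (with JSON config sidecar)
    under ``run.out_dir``.
    """
    out_dir = Path(run.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run.to_yaml(out_dir / "config.yaml")

    if train_data is None:
        train_data = build_dataset(run, "train", run.n_train)
    if val_data is None and run.n_val > 0:
        val_data = build_dataset(run, "test", run.n_val)

    model = build_variant(run.model, seed=run.seed)
    optimizer = Adam(model.parameters(), lr=run.lr)
    rng = np.random.default_rng(run.seed)

    history = []
    best_acc, since_best = -1.0, 0
    log_path = out_dir / "training_log.csv"
    with open(log_path, "w", newline="") as f:
        writer = csv.DictWriter(
            f, fieldnames=["epoch", "class_loss", "recon_loss", "total", "val_accuracy"])
        writer.writeheader()
        for epoch in range(run.epochs):
            stats = _epoch_pass(model, train_data, run, optimizer, rng)
            val_acc = ""
            if val_data is not None:
                val_acc = evaluate(model, val_data).image_level_accuracy
            row = {"epoch": epoch, **{k: f"{v:.6f}" for k, v in stats.items()},
                   "val_accuracy": val_acc}
            writer.writerow(row)
            f.flush()
            history.append({"epoch": epoch, **stats,
                            "val_accuracy": val_acc if val_acc != "" else None})
            if verbose:
                print(f"epoch {epoch}: total={stats['total']:.4f} val={val_acc}")
            if run.patience is not None and val_data is not None:
                if val_acc > best_acc:
                    best_acc, since_best = val_acc, 0
                else:
                    since_best += 1
                    if since_best > run.patience:
                        break
    save_checkpoint(model, out_dir / "checkpoint.npz", seed=run.seed)
    return model, history


def evaluate(model: OCRA, data: Dataset, batch_size: int = 64) -> EvalReport:
    """Image-level accuracy: an image counts as correct only if the full
    predicted label multiset matches the ground truth."""
    cfg = model.config
    if data.task != cfg.task:
        raise ValueError(f"dataset task {data.task!r} != model task {cfg.task!r}")
    correct = 0
    per_class: dict = {}
    with no_grad():
        for start in range(0, len(data), batch_size):
            images = np.asarray(data.images[start:start + batch_size],
                                dtype=np.float64)
            labels = data.labels[start:start + batch_size]
            episode = model.run_episode(images)
            scores = episode.cumulative_scores.data
            if cfg.task == "reasoning":
                preds = predict_same_different(scores, cfg.response_idx)
                for pred, lab in zip(np.atleast_1d(preds), labels):
                    ok = pred == lab[0]
                    correct += ok
                    entry = per_class.setdefault(lab[0], [0, 0])
                    entry[0] += int(ok)
                    entry[1] += 1
            else:
                preds = predict_digits(scores)
                for pred, lab in zip(np.atleast_2d(preds), labels):
                    ok = tuple(int(p) for p in pred) == tuple(sorted(lab))
                    correct += ok
                    for cls in lab:
                        entry = per_class.setdefault(int(cls), [0, 0])
                        entry[0] += int(ok)
                        entry[1] += 1
    return EvalReport(
        image_level_accuracy=correct / max(len(data), 1),
        n_images=len(data),
        per_class_correct={str(k): v for k, v in sorted(per_class.items())},
    )


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean over run accuracies."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        return float(v.mean()), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def visualize(model: OCRA, image: np.ndarray, out_dir: str | Path) -> list[Path]:
    """Per-timestep panels: input with the read window in green, the
    retro-projected glimpse, and the cumulative canvas with the write
    window in red; captions give the most-active capsule and magnitude.
    Returns the per-step PNG paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    cfg = model.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image = np.asarray(image, dtype=np.float64)
    with no_grad():
        episode = model.run_episode(image)

    def _box(pose, n):
        cx = float(np.ravel(pose["center_x"])[0]) - 1  # 1-based -> 0-based
        cy = float(np.ravel(pose["center_y"])[0]) - 1
        half = (n - 1) / 2.0 * float(np.ravel(pose["stride"])[0])
        return cx - half, cy - half, 2 * half, 2 * half

    paths = []
    canvas_cum = np.zeros_like(image)
    for t, trace in enumerate(episode.traces):
        canvas_cum = canvas_cum + trace.canvas_increment.reshape(image.shape)
        fig, axes = plt.subplots(1, 3, figsize=(7.5, 3))
        axes[0].imshow(image, cmap="gray", vmin=0, vmax=1)
        if trace.read_pose is not None:
            x, y, w, h = _box(trace.read_pose, cfg.glimpse_size)
            axes[0].add_patch(Rectangle((x, y), w, h, fill=False,
                                        edgecolor="lime", linewidth=1.5))
        axes[0].set_title("input + read")
        if trace.glimpse is not None:
            axes[1].imshow(trace.glimpse.reshape(cfg.glimpse_size, cfg.glimpse_size),
                           cmap="gray")
        axes[1].set_title("glimpse")
        axes[2].imshow(np.clip(canvas_cum, 0, 1), cmap="gray", vmin=0, vmax=1)
        if trace.write_pose is not None:
            x, y, w, h = _box(trace.write_pose, cfg.patch_size)
            axes[2].add_patch(Rectangle((x, y), w, h, fill=False,
                                        edgecolor="red", linewidth=1.5))
        axes[2].set_title("canvas + write")
        mag = float(np.ravel(trace.class_magnitudes)[int(np.ravel(trace.most_active)[0])]) \
            if trace.class_magnitudes.ndim == 1 else \
            float(trace.class_magnitudes[0, int(np.ravel(trace.most_active)[0])])
        fig.suptitle(f"step {t}: capsule {int(np.ravel(trace.most_active)[0])} "
                     f"mag {mag:.3f}")
        for ax in axes:
            ax.set_xticks([])
            ax.set_yticks([])
        path = out_dir / f"panel_{t:02d}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
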