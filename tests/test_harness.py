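"""Harness: parameter accounting, targets, training loop, evaluation,
aggregation and visualization."""

import csv
import json

import numpy as np
import pytest

from ocra.losses import LossConfig
from ocra.model import ModelConfig, build_variant
from ocra.harness import (
    RunConfig,
    count_parameters,
    targets_for_labels,
    train,
    evaluate,
    visualize,
    mean_sem,
    save_checkpoint,
    load_checkpoint,
)
from ocra.stimuli import Dataset, gen_multimnist, gen_svrt1


# --------------------------------------------------------- parameter counts
def layerwise_reference_count() -> int:
    """Independent shape-arithmetic oracle for the reference configuration."""
    conv = (5 * 5 * 1 * 32 + 32) + (3 * 3 * 32 * 32 + 32)
    enc_lstm = 4 * (512 * (512 + 512) + 512)       # single combined bias
    primary = 512 * 320 + 320
    routing = 40 * 10 * 8 * 16                     # biasless transforms
    dec_lstm = 4 * (512 * (160 + 512) + 512)       # masked 10x16 input
    pose_heads = 2 * (512 * 4 + 4)
    write_patch = 512 * 324 + 324
    return conv + enc_lstm + primary + routing + dec_lstm + pose_heads + write_patch


def test_reference_count_matches_oracle():
    cfg = ModelConfig(task="multimnist", feedback=False)
    assert layerwise_reference_count() == 3_873_260
    assert count_parameters(cfg) == 3_873_260


def test_cnn_subcount():
    m = build_variant(ModelConfig(task="multimnist", feedback=False))
    conv = (m.conv1_w.size + m.conv1_b.size + m.conv2_w.size + m.conv2_b.size)
    assert conv == 10_080  # 832 + 9_248


def test_counts_all_variants_match_shape_arithmetic():
    for task in ("multimnist", "reasoning"):
        for variant in ("full", "recurrent_noglimpse", "feedforward",
                        "no_capsules"):
            cfg = ModelConfig(task=task, variant=variant, feedback=False)
            model = build_variant(cfg)
            total = sum(p.data.size for p in model.parameters().values())
            assert count_parameters(cfg) == total


# ----------------------------------------------------------------- targets
def test_targets_recognition_counts():
    cfg = ModelConfig(task="multimnist", feedback=False)
    t = targets_for_labels([(3, 7), (5, 5)], cfg)
    assert t[0, 3] == 1 and t[0, 7] == 1 and t[0].sum() == 2
    assert t[1, 5] == 2 and t[1].sum() == 2


def test_targets_reasoning_response_capsules():
    cfg = ModelConfig(task="reasoning")
    t = targets_for_labels([("same",), ("different",)], cfg)
    i_same, i_diff = cfg.response_idx
    assert t[0, i_same] == 1 and t[0, i_diff] == 0
    assert t[1, i_same] == 0 and t[1, i_diff] == 1
    assert (t[:, 2:] == -1).all()  # gist/temporary capsules unsupervised


# --------------------------------------------------------------- evaluation
class _StubModel:
    """Always emits ground-truth-shaped scores."""

    def __init__(self, config, answers):
        self.config = config
        self._answers = answers
        self._pos = 0

    def run_episode(self, images):
        n = images.shape[0]
        scores = np.zeros((n, self.config.n_class))
        for i in range(n):
            for cls in self._answers[self._pos + i]:
                scores[i, int(cls)] += 2.0
        self._pos += n
        from ocra.autodiff import Tensor
        from ocra.model import Episode
        return Episode(traces=[], cumulative_scores=Tensor(scores),
                       canvas=Tensor(np.zeros(images.shape)), coverage=None,
                       config=self.config)


def _toy_dataset(labels, task="multimnist", shape=(36, 36)):
    n = len(labels)
    return Dataset(images=np.zeros((n,) + shape, dtype=np.float32),
                   labels=labels, meta=[{}] * n, task=task, split="test")


def test_oracle_stub_gets_perfect_accuracy():
    cfg = ModelConfig(task="multimnist", feedback=False)
    labels = [(3, 7), (1, 2), (5, 5)]
    model = _StubModel(cfg, labels)
    report = evaluate(model, _toy_dataset(labels))
    assert report.image_level_accuracy == 1.0
    assert report.n_images == 3


def test_multiset_match_is_order_free():
    cfg = ModelConfig(task="multimnist", feedback=False)
    model = _StubModel(cfg, [(7, 3)])
    report = evaluate(model, _toy_dataset([(3, 7)]))
    assert report.image_level_accuracy == 1.0


def test_wrong_duplicate_is_incorrect():
    cfg = ModelConfig(task="multimnist", feedback=False)
    model = _StubModel(cfg, [(3, 3)])
    report = evaluate(model, _toy_dataset([(3, 7)]))
    assert report.image_level_accuracy == 0.0


def test_evaluate_rejects_task_mismatch():
    cfg = ModelConfig(task="multimnist", feedback=False)
    model = _StubModel(cfg, [])
    with pytest.raises(ValueError):
        evaluate(model, _toy_dataset([("same",)], task="reasoning",
                                     shape=(64, 64)))


# -------------------------------------------------------------- aggregation
def test_mean_sem_hand_example():
    mean, sem = mean_sem([0.9, 0.92, 0.94, 0.96, 0.98])
    assert mean == pytest.approx(0.94)
    # sample std = sqrt(0.001) -> sem = sqrt(0.001)/sqrt(5)
    assert sem == pytest.approx(np.sqrt(0.001) / np.sqrt(5))
    m2, s2 = mean_sem([0.5])
    assert m2 == 0.5 and s2 == 0.0


# ----------------------------------------------------------------- training
@pytest.fixture(scope="module")
def tiny_run(tmp_path_factory, glyph_source):
    out = tmp_path_factory.mktemp("run")
    run = RunConfig(
        model=ModelConfig(task="multimnist", feedback=False, recurrent_size=32,
                          n_primary=6, primary_dim=4, class_dim=8, timesteps=2),
        loss=LossConfig(lambda_recon=1.0),
        lr=2e-3, batch_size=32, epochs=3, seed=0,
        n_train=96, n_val=0, out_dir=str(out))
    data = gen_multimnist(glyph_source, 96, seed=0)
    model, history = train(run, train_data=data, val_data=None)
    return run, data, model, history, out


def test_training_loss_decreases(tiny_run):
    _, _, _, history, _ = tiny_run
    assert history[-1]["total"] < history[0]["total"]


def test_training_writes_log_and_checkpoint(tiny_run):
    run, _, _, _, out = tiny_run
    with open(out / "training_log.csv") as f:
        rows = list(csv.DictReader(f))
    assert len(rows) == run.epochs
    assert {"epoch", "class_loss", "recon_loss", "total"} <= set(rows[0])
    assert (out / "checkpoint.npz").exists()
    sidecar = json.loads((out / "checkpoint.npz.json").read_text())
    assert sidecar["config"]["task"] == "multimnist"


def test_training_deterministic(tmp_path, glyph_source, tiny_run):
    run, data, _, history, _ = tiny_run
    run2 = RunConfig(**{**run.__dict__, "out_dir": str(tmp_path)})
    _, history2 = train(run2, train_data=data, val_data=None)
    assert history2[-1]["total"] == pytest.approx(history[-1]["total"], abs=0.0)


def test_checkpoint_roundtrip(tiny_run, tmp_path, rng):
    _, _, model, _, _ = tiny_run
    path = tmp_path / "ck.npz"
    save_checkpoint(model, path, seed=0)
    loaded = load_checkpoint(path)
    x = rng.random((2, 36, 36))
    a = model.run_episode(x).cumulative_scores.data
    b = loaded.run_episode(x).cumulative_scores.data
    np.testing.assert_array_equal(a, b)


def test_multi_seed_reporting():
    accs = [0.2, 0.4, 0.6, 0.5, 0.3]
    mean, sem = mean_sem(accs)
    assert mean == pytest.approx(np.mean(accs))
    assert sem == pytest.approx(np.std(accs, ddof=1) / np.sqrt(5))


def test_reasoning_training_smoke(tmp_path):
    run = RunConfig(
        model=ModelConfig(task="reasoning", recurrent_size=32, n_primary=4,
                          primary_dim=4, class_dim=8, timesteps=2),
        loss=LossConfig(),
        lr=1e-3, batch_size=16, epochs=1, seed=0,
        n_train=32, n_val=0, out_dir=str(tmp_path))
    data = gen_svrt1(32, seed=0)
    model, history = train(run, train_data=data, val_data=None)
    report = evaluate(model, gen_svrt1(16, seed=1, split="test"))
    assert 0.0 <= report.image_level_accuracy <= 1.0


def test_run_config_yaml_roundtrip(tmp_path):
    run = RunConfig(model=ModelConfig(task="reasoning", timesteps=4),
                    loss=LossConfig(margin=0.2), lr=5e-4, epochs=2,
                    out_dir=str(tmp_path))
    path = tmp_path / "cfg.yaml"
    run.to_yaml(path)
    loaded = RunConfig.from_yaml(path)
    assert loaded.model == run.model
    assert loaded.loss == run.loss
    assert loaded.lr == run.lr


# ------------------------------------------------------------ visualization
def test_visualize_panels(tiny_run, tmp_path, rng):
    _, _, model, _, _ = tiny_run
    paths = visualize(model, rng.random((36, 36)), tmp_path)
    assert len(paths) == model.config.timesteps
    for p in paths:
        assert p.exists() and p.stat().st_size > 0


def test_visualize_magnitudes_in_range(tiny_run, rng):
    _, _, model, _, _ = tiny_run
    ep = model.run_episode(rng.random((36, 36)))
    for trace in ep.traces:
        mags = np.ravel(trace.class_magnitudes)
        assert (mags >= 0).all() and (mags < 1).all()
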