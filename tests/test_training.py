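"""Splits, optimization protocol and best-checkpoint restoration."""

import numpy as np
import pytest

from eegfusion.model import build_model
from eegfusion.preprocessing import WindowedDataset
from eegfusion.training import (
    TrainConfig,
    TrainingDiverged,
    session_split,
    split_dataset,
    split_indices,
    train,
)


def _dataset(n, c=2, w=8, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    return WindowedDataset(
        rng.standard_normal((n, c, w)),
        rng.integers(0, n_classes, n),
        [f"cls{i}" for i in range(n_classes)],
        100.0,
    )


# -- random split ------------------------------------------------------------

def test_split_sizes_follow_floor_arithmetic():
    tr, va, te = split_indices(37080, (0.7, 0.1, 0.2), seed=0)
    assert (len(tr), len(va), len(te)) == (25956, 3708, 7416)


def test_split_is_a_partition():
    tr, va, te = split_indices(101, (0.7, 0.1, 0.2), seed=3)
    allidx = np.concatenate([tr, va, te])
    assert len(allidx) == 101
    assert set(allidx.tolist()) == set(range(101))


def test_same_seed_gives_identical_partition():
    a = split_indices(500, (0.7, 0.1, 0.2), seed=11)
    b = split_indices(500, (0.7, 0.1, 0.2), seed=11)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    c = split_indices(500, (0.7, 0.1, 0.2), seed=12)
    assert not np.array_equal(a[0], c[0])


def test_degenerate_fractions_rejected():
    with pytest.raises(ValueError):
        TrainConfig(split_fractions=(1.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="empty"):
        split_indices(5, (0.7, 0.1, 0.2), seed=0)


def test_split_dataset_partitions_windows():
    data = _dataset(50)
    tr, va, te = split_dataset(data, TrainConfig(seed=5))
    assert tr.n_windows + va.n_windows + te.n_windows == 50
    assert (tr.n_windows, va.n_windows, te.n_windows) == (35, 5, 10)


def test_stratified_split_covers_every_group():
    data = _dataset(60)
    groups = np.repeat([0, 1, 2], 20)
    tr, va, te = split_dataset(data, TrainConfig(seed=1), stratify_by=groups)
    assert tr.n_windows + va.n_windows + te.n_windows == 60
    # with 20 windows per group each partition gets 14/2/4 from every group
    assert (tr.n_windows, va.n_windows, te.n_windows) == (42, 6, 12)


# -- session split -----------------------------------------------------------

def test_session_split_one_train_one_test():
    sessions = {"s1": _dataset(12, seed=1), "s2": _dataset(10, seed=2)}
    tr, te = session_split(sessions, ["s1"], ["s2"])
    assert tr.n_windows == 12 and te.n_windows == 10


def test_session_split_three_train_two_test():
    sessions = {f"s{i}": _dataset(6, seed=i) for i in range(1, 6)}
    tr, te = session_split(sessions, ["s1", "s2", "s3"], ["s4", "s5"])
    assert tr.n_windows == 18 and te.n_windows == 12


def test_overlapping_sessions_rejected():
    sessions = {"s1": _dataset(6), "s2": _dataset(6)}
    with pytest.raises(ValueError, match="both"):
        session_split(sessions, ["s1"], ["s1", "s2"])


def test_unknown_session_rejected():
    with pytest.raises(ValueError, match="unknown"):
        session_split({"s1": _dataset(6)}, ["s1"], ["s9"])


# -- training loop -----------------------------------------------------------

def _separable_windows(n, seed=0):
    """Two classes distinguished by the sign of a strong channel offset."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    x = rng.standard_normal((n, 8, 80)).astype(np.float32)
    x[labels == 0, :4, :] += 2.0
    x[labels == 1, 4:, :] += 2.0
    return WindowedDataset(x, labels, ["left", "right"], 160.0)


def test_small_dataset_is_overfit_to_perfect_training_accuracy(tiny_spec):
    data = _separable_windows(32, seed=7)
    net, _ = build_model(tiny_spec, seed=7)
    cfg = TrainConfig(learning_rate=5e-3, batch_size=8, max_epochs=30, seed=7)
    result = train(net, data, data, cfg)
    assert result.history[-1]["train_acc"] == 1.0


def test_history_length_matches_epochs_run(tiny_spec):
    data = _separable_windows(24, seed=1)
    net, _ = build_model(tiny_spec, seed=1)
    cfg = TrainConfig(learning_rate=1e-3, batch_size=8, max_epochs=4, seed=1)
    result = train(net, data, data, cfg)
    assert len(result.history) == 4
    assert set(result.history[0]) == {
        "train_loss", "train_acc", "val_loss", "val_acc"
    }


def test_zero_epochs_rejected(tiny_spec):
    data = _separable_windows(16)
    net, _ = build_model(tiny_spec, seed=0)
    with pytest.raises(ValueError, match="max_epochs"):
        train(net, data, data, TrainConfig(max_epochs=0))


def test_restored_weights_reproduce_best_validation_accuracy(tiny_spec):
    """After training, the returned model carries the checkpoint of the
    best epoch: re-evaluating the validation set must reproduce the
    maximum recorded validation accuracy exactly."""
    tr = _separable_windows(48, seed=3)
    va = _separable_windows(16, seed=4)
    net, _ = build_model(tiny_spec, seed=3)
    cfg = TrainConfig(learning_rate=2e-3, batch_size=8, max_epochs=6, seed=3)
    result = train(net, tr, va, cfg)
    best = max(h["val_acc"] for h in result.history)
    assert result.history[result.best_epoch]["val_acc"] == best
    # first occurrence on ties
    assert all(h["val_acc"] < best for h in result.history[: result.best_epoch])
    re_eval = (net.predict_proba(va.windows).argmax(axis=1) == va.labels).mean()
    assert abs(re_eval - best) < 1e-6


def test_checkpoint_written_to_disk(tiny_spec, tmp_path):
    data = _separable_windows(24, seed=5)
    net, _ = build_model(tiny_spec, seed=5)
    cfg = TrainConfig(learning_rate=1e-3, batch_size=8, max_epochs=2, seed=5)
    result = train(net, data, data, cfg, checkpoint_path=tmp_path / "ck.npz")
    assert result.best_weights_path is not None
    other, _ = build_model(tiny_spec, seed=99)
    other.load_weights(result.best_weights_path)
    x = data.windows[:4]
    np.testing.assert_array_equal(
        other.predict_proba(x), net.predict_proba(x)
    )


def test_divergence_aborts_with_diagnostic(tiny_spec):
    data = _separable_windows(16, seed=6)
    net, _ = build_model(tiny_spec, seed=6)
    cfg = TrainConfig(learning_rate=1e18, batch_size=8, max_epochs=5, seed=6)
    with np.errstate(all="ignore"), pytest.raises(TrainingDiverged):
        train(net, data, data, cfg)
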