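"""Splitting, optimization and best-checkpoint training protocol.

Two partition schemes: a seed-determined uniformly random 70/10/20
window split (pooled multi-subject data) and a session-level split for
datasets recorded in separate sessions. Training runs Adam against
binary (two-class) or categorical cross-entropy, evaluates validation
accuracy after every epoch, checkpoints on improvement, and restores the
best weights at the end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .preprocessing import EpochSet, WindowedDataset

logger = logging.getLogger(__name__)


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the published protocol
    (Adam, learning rate 1e-5, binary cross-entropy, 70/10/20 split,
    fixed seed). Batch size and epoch budget are implementation choices."""

    learning_rate: float = 1e-5
    loss: str = "binary_crossentropy"
    batch_size: int = 16
    max_epochs: int = 100
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0
    checkpoint_metric: str = "val_accuracy"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss not in nn.LOSSES:
            raise ValueError(f"loss must be one of {sorted(nn.LOSSES)}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        fr = self.split_fractions
        if len(fr) != 3 or any(not 0 < f < 1 for f in fr):
            raise ValueError("split_fractions must be three values in (0, 1)")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.checkpoint_metric != "val_accuracy":
            raise ValueError("only val_accuracy checkpointing is supported")


@dataclass
class TrainResult:
    """Per-epoch history plus the best-validation checkpoint."""

    best_epoch: int
    history: list[dict[str, float]]
    best_weights_path: Path | None

    @property
    def best_val_accuracy(self) -> float:
        return self.history[self.best_epoch]["val_acc"]


def split_indices(
    n: int, fractions: tuple[float, float, float], seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed-determined random partition. Validation and test sizes are
    floor(fraction * n); the remainder goes to training."""
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n} windows at {fractions} leaves an empty partition"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return (
        perm[:n_train],
        perm[n_train : n_train + n_val],
        perm[n_train + n_val :],
    )


def split_dataset(
    data: WindowedDataset, config: TrainConfig,
    stratify_by: np.ndarray | None = None,
) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Random train/val/test split of pooled windows.

    With ``stratify_by`` (e.g. a per-window subject id) the split is done
    independently within each group and concatenated, so every group
    contributes to every partition.
    """
    if stratify_by is None:
        tr, va, te = split_indices(data.n_windows, config.split_fractions, config.seed)
    else:
        stratify_by = np.asarray(stratify_by)
        if stratify_by.shape != (data.n_windows,):
            raise ValueError("stratify_by must have one entry per window")
        parts: list[list[np.ndarray]] = [[], [], []]
        for g, group in enumerate(np.unique(stratify_by)):
            idx = np.flatnonzero(stratify_by == group)
            sub = split_indices(idx.size, config.split_fractions, config.seed + g)
            for part, s in zip(parts, sub):
                part.append(idx[s])
        tr, va, te = (np.concatenate(p) for p in parts)
    return data.subset(tr), data.subset(va), data.subset(te)


def session_split(
    sessions: dict[str, WindowedDataset | EpochSet],
    train_sessions: list[str],
    test_sessions: list[str],
):
    """Concatenate named sessions into disjoint train/test sets."""
    overlap = set(train_sessions) & set(test_sessions)
    if overlap:
        raise ValueError(f"sessions {sorted(overlap)} appear in both lists")
    missing = (set(train_sessions) | set(test_sessions)) - set(sessions)
    if missing:
        raise ValueError(f"unknown session(s): {sorted(missing)}")

    def _concat(names: list[str]):
        items = [sessions[n] for n in names]
        first = items[0]
        if isinstance(first, WindowedDataset):
            prov, off = [], 0
            for it in items:
                prov.append(it.provenance + np.array([off, 0]))
                off += int(it.provenance[:, 0].max()) + 1 if it.n_windows else 0
            return WindowedDataset(
                np.concatenate([it.windows for it in items]),
                np.concatenate([it.labels for it in items]),
                list(first.class_names),
                first.sampling_rate_hz,
                np.concatenate(prov),
            )
        return EpochSet(
            np.concatenate([it.epochs for it in items]),
            np.concatenate([it.labels for it in items]),
            list(first.class_names),
            first.sampling_rate_hz,
        )

    return _concat(train_sessions), _concat(test_sessions)


def _accuracy(net: nn.FusionNetwork, data: WindowedDataset) -> float:
    proba = net.predict_proba(data.windows)
    return float((proba.argmax(axis=1) == data.labels).mean())


def train(
    net: nn.FusionNetwork,
    train_data: WindowedDataset,
    val_data: WindowedDataset,
    config: TrainConfig,
    checkpoint_path: str | Path | None = None,
) -> TrainResult:
    """Optimize, checkpoint on best validation accuracy, restore best.

    One seeded generator drives batch shuffling; dropout draws from the
    generators baked into the network at construction. History has one
    entry per epoch actually run. The best epoch is the first occurrence
    of the maximum validation accuracy; its weights (including batch-norm
    moving statistics) are restored into ``net`` before returning.
    """
    if config.max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    if val_data.n_windows == 0:
        raise ValueError("validation set must be non-empty")
    n_classes = net.head.params["b"].shape[0]
    if config.loss == "binary_crossentropy" and n_classes > 2:
        logger.warning(
            "binary cross-entropy with %d mutually exclusive classes; "
            "categorical_crossentropy is the appropriate loss", n_classes
        )
    loss_fn = nn.LOSSES[config.loss]
    x = np.asarray(train_data.windows, dtype=np.float32)[..., None]
    y = np.eye(n_classes, dtype=np.float32)[train_data.labels]
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(net, config.learning_rate)

    history: list[dict[str, float]] = []
    best_epoch, best_val, best_weights = -1, -np.inf, None
    for epoch in range(config.max_epochs):
        order = rng.permutation(x.shape[0])
        losses, correct = [], 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = net.forward(x[idx], training=True)
            loss, dz = loss_fn(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}"
                )
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == train_data.labels[idx]).sum())
            net.backward(dz)
            opt.step()
        val_logits = net.predict_proba(val_data.windows)
        val_acc = float((val_logits.argmax(axis=1) == val_data.labels).mean())
        val_loss, _ = loss_fn(
            np.log(np.clip(val_logits, 1e-12, None)),
            np.eye(n_classes, dtype=np.float32)[val_data.labels],
        )
        entry = {
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / x.shape[0],
            "val_loss": float(val_loss),
            "val_acc": val_acc,
        }
        history.append(entry)
        if val_acc > best_val:
            best_val, best_epoch = val_acc, epoch
            best_weights = net.get_weights()
        logger.info(
            "epoch %d: train_loss=%.4f train_acc=%.3f val_acc=%.3f%s",
            epoch, entry["train_loss"], entry["train_acc"], val_acc,
            " *" if best_epoch == epoch else "",
        )

    net.set_weights(best_weights)
    path = None
    if checkpoint_path is not None:
        path = Path(checkpoint_path)
        net.save_weights(path)
    return TrainResult(best_epoch=best_epoch, history=history, best_weights_path=path)
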