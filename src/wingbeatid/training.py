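"""Training protocol: Adam + triangular cyclical learning rate, per-epoch
checkpointing, best-checkpoint selection by validation accuracy, and
post-hoc decision-threshold tuning.

The learning rate rises linearly from ``clr_base`` (1e-4) to ``clr_max``
(1e-2) over ``clr_step_size`` iterations and falls back symmetrically
(period = 2 * step size). One checkpoint is recorded per epoch; the one
with the highest validation accuracy at the fixed 0.5 threshold is
restored (earliest epoch on ties). Only after selection is the decision
threshold tuned, by maximizing balanced accuracy on the validation scores.

The loss is binary cross-entropy on the single sigmoid output — the
two-class case of categorical cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentConfig, augment_pipeline
from .evaluation import balanced_accuracy


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    clr_base: float = 1e-4
    clr_max: float = 1e-2
    clr_step_size: int | None = None  # iterations per half-cycle; None = 4 epochs
    seed: int = 0
    augment: bool = False
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.clr_base < self.clr_max:
            raise ValueError("clr_base must be below clr_max")


@dataclass
class TrainResult:
    history: pd.DataFrame           # per-epoch train/val loss and accuracy
    checkpoints: list               # per-epoch parameter snapshots (or paths)
    selected_epoch: int             # 1-based, earliest maximum val accuracy
    tuned_threshold: float
    model: nn.Network               # with the selected checkpoint restored


def clr_schedule(iteration: int, config: TrainConfig,
                 step_size: int | None = None) -> float:
    """Triangular cyclical learning rate at a 0-based iteration index."""
    step = step_size if step_size is not None else config.clr_step_size
    if step is None or step <= 0:
        raise ValueError("clr_step_size must be a positive integer")
    cycle = np.floor(1 + iteration / (2 * step))
    x = np.abs(iteration / step - 2 * cycle + 1)
    return float(config.clr_base + (config.clr_max - config.clr_base)
                 * max(0.0, 1.0 - x))


def select_checkpoint(val_accuracies: list[float]) -> int:
    """1-based index of the earliest maximum validation accuracy."""
    accs = np.asarray(val_accuracies)
    return int(np.argmax(accs)) + 1


def tune_threshold(val_scores: np.ndarray, val_labels: np.ndarray) -> float:
    """Decision threshold maximizing balanced accuracy on validation data.

    Candidates are the midpoints between consecutive sorted unique scores
    plus {0, 0.5, 1}; scores >= threshold predict SWD. Ties go to the
    candidate closest to 0.5 (then the smaller).
    """
    scores = np.asarray(val_scores, dtype=np.float64)
    y = np.asarray(val_labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold tuning needs both classes in the labels")
    uniq = np.unique(scores)
    candidates = np.unique(np.r_[0.0, 0.5, 1.0, (uniq[:-1] + uniq[1:]) / 2])
    best_thr, best_ba = 0.5, -1.0
    for thr in candidates:
        ba = balanced_accuracy(y, (scores >= thr).astype(int))
        better = ba > best_ba + 1e-12
        tie = abs(ba - best_ba) <= 1e-12 and (
            abs(thr - 0.5) < abs(best_thr - 0.5) - 1e-12
            or (abs(abs(thr - 0.5) - abs(best_thr - 0.5)) <= 1e-12 and thr < best_thr))
        if better or tie:
            best_thr, best_ba = float(thr), max(ba, best_ba)
    return best_thr


def _accuracy(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
              ) -> float:
    return float(np.mean((scores >= threshold).astype(int) == labels))


def _bce(scores: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(scores, 1e-12, 1 - 1e-12)
    y = labels
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def train_model(model: nn.Network,
                train_set: tuple[np.ndarray, np.ndarray],
                val_set: tuple[np.ndarray, np.ndarray],
                config: TrainConfig,
                checkpoint_dir: str | Path | None = None) -> TrainResult:
    """Run the full training protocol and return the selected model.

    ``train_set``/``val_set`` are ``(x, labels)`` with labels 0 = DM,
    1 = SWD and ``x`` shaped (records, 1, length) or (records, 1, H, W).
    Waveform augmentation, when enabled, is applied on the fly to training
    batches only.
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("empty train or validation set")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    y_train = np.asarray(y_train).astype(np.float64)
    y_val = np.asarray(y_val).astype(np.float64)

    n = x_train.shape[0]
    iters_per_epoch = int(np.ceil(n / config.batch_size))
    step_size = (config.clr_step_size if config.clr_step_size is not None
                 else 4 * iters_per_epoch)

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.parameters())
    checkpoint_dir = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if checkpoint_dir is not None:
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    checkpoints: list = []
    iteration = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_losses, epoch_correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x_train[idx]
            if config.augment:
                xb = xb.copy()
                flat = xb.reshape(xb.shape[0], -1)
                for i in range(flat.shape[0]):
                    flat[i] = augment_pipeline(flat[i], rng,
                                               config.augment_config)
            yb = y_train[idx]
            optimizer.zero_grad()
            logits = model.forward(xb.astype(np.float32, copy=False), train=True)
            loss, dlogits = nn.bce_with_logits(logits, yb)
            model.backward(dlogits.astype(logits.dtype))
            optimizer.step(clr_schedule(iteration, config, step_size))
            iteration += 1
            epoch_losses.append(loss)
            epoch_correct += int(np.sum((nn.sigmoid(logits).ravel() >= 0.5)
                                        == (yb >= 0.5)))

        val_scores = model.predict_proba(x_val)
        row = {"epoch": epoch,
               "train_loss": float(np.mean(epoch_losses)),
               "train_acc": epoch_correct / n,
               "val_loss": _bce(val_scores, y_val),
               "val_acc": _accuracy(val_scores, y_val)}
        rows.append(row)

        state = model.clone_state()
        if checkpoint_dir is not None:
            path = checkpoint_dir / f"epoch{epoch:03d}_valacc{row['val_acc']:.4f}.npz"
            np.savez_compressed(path, *state)
            checkpoints.append(path)
        else:
            checkpoints.append(state)

    history = pd.DataFrame(rows)
    selected = select_checkpoint(history["val_acc"].tolist())
    chosen = checkpoints[selected - 1]
    if checkpoint_dir is not None:
        data = np.load(chosen)
        state = [data[k] for k in data.files]
    else:
        state = chosen
    model.load_state(state)

    tuned = tune_threshold(model.predict_proba(x_val), y_val.astype(int))
    return TrainResult(history=history, checkpoints=checkpoints,
                       selected_epoch=selected, tuned_threshold=tuned,
                       model=model)
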