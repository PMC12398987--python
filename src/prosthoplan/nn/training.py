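"""Training protocol: Adam, plateau LR halving, early stopping.

The defaults reproduce the study protocol: categorical cross-entropy,
Adam at 1e-3, learning rate halved after 5 epochs without validation
improvement down to a floor of 1e-7, early stopping after 10 epochs
without improvement with the best weights restored, at most 200 epochs,
batch size 32, and an inner 80/20 train/validation split of the N_cal
cases drawn for the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..generate import CaseCollection
from .model import Sequential, Adam

__all__ = ["TrainingConfig", "TrainingHistory", "train_model"]


@dataclass(frozen=True)
class TrainingConfig:
    initial_lr: float = 1e-3
    lr_factor: float = 0.5
    lr_halving_patience: int = 5
    lr_floor: float = 1e-7
    early_stop_patience: int = 10
    restore_best: bool = True
    max_epochs: int = 200
    batch_size: int = 32
    val_fraction: float = 0.2
    seed: int = 0


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    stopped_epoch: int = 0   # 1-based count of epochs actually run
    best_epoch: int = 0      # 1-based epoch with the lowest validation loss


def _as_arrays(cases) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(cases, CaseCollection):
        return cases.encoded()
    x, y = cases
    return np.asarray(x), np.asarray(y)


def train_model(
    model: Sequential,
    cases: CaseCollection | tuple[np.ndarray, np.ndarray],
    config: TrainingConfig | None = None,
) -> tuple[Sequential, TrainingHistory]:
    """Train in place under the study protocol; returns (model, history).

    ``cases`` is the N_cal draw for this run, either a case collection or
    a pre-encoded ``(X, y)`` pair of integer arrays.  The 80/20 inner
    split, batch shuffling and dropout masks all derive from
    ``config.seed``.
    """
    cfg = config or TrainingConfig()
    X, y = _as_arrays(cases)
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 cases for an 80/20 split, got {n}")

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, yt = X[train_idx], y[train_idx]
    Xv, yv = X[val_idx], y[val_idx]

    optimizer = Adam(model, lr=cfg.initial_lr)
    history = TrainingHistory()
    best_val = math.inf
    best_weights = model.get_weights() if cfg.restore_best else None
    lr_wait = 0
    stop_wait = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(Xt))
        batch_losses = []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            loss = model.loss_and_grad(Xt[idx], yt[idx], rng)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            optimizer.step()
            batch_losses.append(loss)

        val_loss = model.loss(Xv, yv)
        if not math.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(val_loss)
        history.learning_rate.append(optimizer.lr)
        history.stopped_epoch = epoch

        if val_loss < best_val:  # strict improvement, zero tolerance
            best_val = val_loss
            history.best_epoch = epoch
            if cfg.restore_best:
                best_weights = model.get_weights()
            lr_wait = 0
            stop_wait = 0
        else:
            lr_wait += 1
            stop_wait += 1
            if lr_wait >= cfg.lr_halving_patience and optimizer.lr > cfg.lr_floor:
                optimizer.lr = max(optimizer.lr * cfg.lr_factor, cfg.lr_floor)
                lr_wait = 0
            if stop_wait >= cfg.early_stop_patience:
                break

    if cfg.restore_best and best_weights is not None:
        model.set_weights(best_weights)
    return model, history
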