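"""Generic mini-batch training loop with validation-loss early stopping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .layers import Module
from .optim import Adam


@dataclass
class TrainConfig:
    """Optimization settings shared by the auto-encoder and the classifiers.

    ``patience`` follows the convention that training stops after that many
    consecutive epochs without a strict improvement of the validation loss,
    and the parameters from the best-validation epoch are restored.
    """

    max_epochs: int = 200
    patience: int = 100
    lr: float = 1e-3
    batch_size: int = 128
    l2_coeff: float = 1e-4
    seed: int = 0
    shuffle: bool = True


class EarlyStopper:
    """Tracks the best validation loss; signals stop after `patience` stalls."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.stalled = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record `loss` for `epoch` (1-based); return True when training
        should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            self.stalled = 0
        else:
            self.stalled += 1
        return self.stalled >= self.patience


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
        }


def fit(
    model: Module,
    batch_loss: Callable,
    train_arrays: tuple[np.ndarray, ...],
    val_arrays: tuple[np.ndarray, ...],
    cfg: TrainConfig,
    no_decay: list | None = None,
) -> History:
    """Minimize ``batch_loss(model, *batch, training, rng)`` with Adam.

    ``batch_loss`` must return an autodiff scalar in training mode and is
    reused (with ``training=False``) for full-pass validation loss.  The
    model is left holding the best-validation-epoch parameters.
    """
    n = train_arrays[0].shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if val_arrays[0].shape[0] == 0:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.l2_coeff,
               no_decay=no_decay)
    stopper = EarlyStopper(cfg.patience)
    history = History()
    best_state = model.state()

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = tuple(a[idx] for a in train_arrays)
            opt.zero_grad()
            loss = batch_loss(model, *batch, training=True, rng=rng)
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        history.train_loss.append(epoch_loss / n_batches)

        val = batch_loss(model, *val_arrays, training=False, rng=rng)
        vloss = val.item()
        history.val_loss.append(vloss)
        improved = vloss < stopper.best_loss
        stop = stopper.update(epoch, vloss)
        if improved:
            best_state = model.state()
        if stop:
            break

    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = len(history.val_loss)
    model.load_state(best_state)
    return history
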