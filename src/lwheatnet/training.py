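"""Training: cross-entropy loss, momentum SGD and cosine-annealing schedule.

The optimiser follows the exponential-moving-average momentum form

    V_t = beta * V_{t-1} + (1 - beta) * g,      theta <- theta - eta * V_t

(the update as published; note it differs from the common framework form
``V = beta*V + g`` by a factor (1 - beta) on the gradient — a
``ema_momentum=False`` switch selects the common form).  Weight decay enters
as an L2 term added to the gradient before the momentum update.

The learning rate follows cosine annealing with warm restarts,

    eta_t = eta_min + (eta_max - eta_min) * (1 + cos(pi * T_cur / T_i)) / 2,

where the eta bounds are expressed as fractions of the base learning rate
(defaults 1 and 0.01, so the default schedule spans 3e-3 down to 3e-5 over
one 50-epoch cycle).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import LWheatNet
from .nn import softmax

__all__ = [
    "ScheduleConfig",
    "TrainConfig",
    "TrainState",
    "cross_entropy",
    "batch_loss",
    "cosine_lr",
    "momentum_step",
    "evaluate_loss_accuracy",
    "fit",
    "write_history_csv",
]

_LOG_CLAMP = 1e-12  # floor on predicted probabilities before the log


@dataclass
class ScheduleConfig:
    """Cosine-annealing bounds as fractions of the base learning rate and the
    cycle length in epochs."""

    eta_max_frac: float = 1.0
    eta_min_frac: float = 0.01
    cycle_epochs: int = 50

    def __post_init__(self):
        if not 0.0 <= self.eta_min_frac < self.eta_max_frac:
            raise ValueError("require 0 <= eta_min_frac < eta_max_frac")
        if self.cycle_epochs < 1:
            raise ValueError("cycle_epochs must be >= 1")


@dataclass
class TrainConfig:
    """Run hyperparameters; defaults are the published settings (batch 16,
    50 epochs, base LR 3e-3, momentum 0.9, weight decay 4e-5)."""

    batch_size: int = 16
    epochs: int = 50
    base_lr: float = 3e-3
    momentum_beta: float = 0.9
    weight_decay: float = 4e-5
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    seed: int = 0
    ema_momentum: bool = True

    def __post_init__(self):
        if not 0.0 <= self.momentum_beta < 1.0:
            raise ValueError("momentum_beta must be in [0, 1)")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if isinstance(self.schedule, dict):
            self.schedule = ScheduleConfig(**self.schedule)


@dataclass
class TrainState:
    """Mutable optimisation state: the model's parameters, one zero-initialised
    momentum buffer per parameter, the epoch counter, the RNG and the per-epoch
    history."""

    model: LWheatNet
    velocities: dict[str, np.ndarray]
    epoch: int = 0
    rng: np.random.Generator | None = None
    history: list[dict] = field(default_factory=list)

    @classmethod
    def init(cls, model: LWheatNet, seed: int = 0) -> "TrainState":
        velocities = {name: np.zeros_like(p.data)
                      for name, p in model.named_parameters()}
        return cls(model=model, velocities=velocities,
                   rng=np.random.default_rng(seed))


def cross_entropy(predicted_probs, true_onehot) -> float:
    """Cross-entropy −Σ y_i log(ŷ_i) for one sample.

    Probabilities are clamped below at 1e-12 before the log, so a zero
    predicted probability for the true class yields a large finite loss
    rather than an infinity.
    """
    p = np.asarray(predicted_probs, dtype=np.float64)
    y = np.asarray(true_onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {y.shape}")
    return float(-(y * np.log(np.clip(p, _LOG_CLAMP, None))).sum())


def batch_loss(per_sample_losses) -> float:
    """Arithmetic mean of per-sample losses."""
    losses = np.asarray(per_sample_losses, dtype=np.float64)
    if losses.size == 0:
        raise ValueError("batch_loss of an empty batch is undefined")
    return float(losses.mean())


def cosine_lr(t_cur: int, sched: ScheduleConfig, base_lr: float) -> float:
    """Learning rate at epoch ``t_cur`` under cosine annealing with warm
    restarts: past the end of a cycle the phase wraps around (the rate jumps
    back to its maximum)."""
    t_i = sched.cycle_epochs
    if t_i <= 0:
        raise ValueError("cycle_epochs must be positive")
    if t_cur > t_i:
        t_cur = t_cur % t_i
    frac = sched.eta_min_frac + (sched.eta_max_frac - sched.eta_min_frac) * (
        1.0 + math.cos(math.pi * t_cur / t_i)) / 2.0
    return base_lr * frac


def momentum_step(state: TrainState, gradients: dict[str, np.ndarray],
                  lr: float, beta: float = 0.9, weight_decay: float = 0.0,
                  ema: bool = True) -> TrainState:
    """One momentum-SGD update of every parameter in place.

    ``gradients`` maps parameter names to gradient arrays (shapes must match).
    Weight decay is added to the gradient first; then the momentum buffer is
    updated (EMA form by default) and the parameter is decremented by
    ``lr * V``.
    """
    params = dict(state.model.named_parameters())
    for name, g in gradients.items():
        p = params[name]
        v = state.velocities[name]
        if g.shape != p.data.shape:
            raise ValueError(f"gradient shape {g.shape} does not match parameter "
                             f"{name} shape {p.data.shape}")
        if weight_decay:
            g = g + weight_decay * p.data
        if ema:
            v *= beta
            v += (1.0 - beta) * g
        else:
            v *= beta
            v += g
        p.data -= lr * v
    return state


def _loss_and_accuracy(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    p_true = np.clip(probs[np.arange(len(labels)), labels], _LOG_CLAMP, None)
    loss = float(-np.log(p_true).mean())
    acc = float((probs.argmax(axis=1) == labels).mean())
    return loss, acc


def evaluate_loss_accuracy(model: LWheatNet, x: np.ndarray, y: np.ndarray,
                           batch_size: int = 64) -> tuple[float, float]:
    """Mean cross-entropy and accuracy in evaluation mode."""
    probs = model.predict_proba(x, batch_size=batch_size)
    return _loss_and_accuracy(probs, y)


def fit(model: LWheatNet, train_data: tuple[np.ndarray, np.ndarray],
        cfg: TrainConfig,
        val_data: tuple[np.ndarray, np.ndarray] | None = None,
        log_path=None) -> TrainState:
    """Train ``model`` for ``cfg.epochs`` epochs of shuffled mini-batches.

    ``train_data`` is an ``(X, y)`` pair with X of shape (N, 3, H, W) and
    integer labels y.  All randomness (shuffling, dropout) is drawn from a
    generator seeded with ``cfg.seed``, so two runs with identical inputs and
    seeds produce bit-identical histories and parameters.  Per-epoch rows
    (epoch, lr, train_loss, train_acc, val_loss, val_acc) are recorded in
    ``state.history`` and optionally written to ``log_path`` as CSV.
    """
    x, y = train_data
    n = len(x)
    if n == 0:
        raise ValueError("cannot fit on an empty training set")
    num_classes = model.config.num_classes
    state = TrainState.init(model, cfg.seed)
    model.attach_rng(state.rng)
    eye = np.eye(num_classes, dtype=x.dtype)

    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.schedule, cfg.base_lr)
        order = state.rng.permutation(n)
        loss_sum = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            probs = softmax(logits)
            loss, _ = _loss_and_accuracy(probs, yb)
            dlogits = (probs - eye[yb]) / len(idx)
            model.zero_grad()
            model.backward(dlogits.astype(logits.dtype))
            grads = {name: p.grad for name, p in model.named_parameters()}
            momentum_step(state, grads, lr, cfg.momentum_beta,
                          cfg.weight_decay, cfg.ema_momentum)
            loss_sum += loss * len(idx)
            correct += int((probs.argmax(axis=1) == yb).sum())
        row = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": loss_sum / n,
            "train_acc": correct / n,
            "val_loss": float("nan"),
            "val_acc": float("nan"),
        }
        if val_data is not None:
            row["val_loss"], row["val_acc"] = evaluate_loss_accuracy(
                model, val_data[0], val_data[1])
        state.history.append(row)
        state.epoch = epoch + 1

    if log_path is not None:
        write_history_csv(state.history, log_path)
    return state


def write_history_csv(history: list[dict], path) -> None:
    """Per-epoch training log (epoch, lr, train_loss, train_acc, val_loss,
    val_acc) as CSV."""
    fields = ["epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for row in history:
            writer.writerow({k: row.get(k, "") for k in fields})
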