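"""Seeded mini-batch SGD training with cross-entropy loss.

The reference protocol trains for 100 epochs with batches of 512 beats at a
constant learning rate of 0.001; a reduced "fixture" profile (small synthetic
cohort, 10 epochs, batch 64) exists for fast CPU experiments.  Momentum 0.9
is this package's default — plain SGD is available via ``momentum=0``.

Training is bit-reproducible: shuffling and initialization are driven by
named seeds, and :class:`TrainHistory` carries a SHA-256 digest of the final
parameters so two runs can be compared exactly.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field

import numpy as np

from . import nn


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 512
    epochs: int = 100
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0
    seed: int = 0
    shuffle: bool = True
    warmup_epochs: int = 0
    cooldown_epochs: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.cooldown_epochs < self.epochs:
            raise ValueError("cooldown_epochs must be in [0, epochs)")
        if not 0 <= self.warmup_epochs < self.epochs - self.cooldown_epochs:
            raise ValueError("warmup_epochs must fit before the cooldown")

    @staticmethod
    def fixture(seed: int = 0) -> "TrainConfig":
        """Reduced profile for the synthetic CPU experiments: short schedule,
        small batches, mild weight decay, and a final low-rate cooldown so
        the run settles instead of ending mid-oscillation."""
        return TrainConfig(batch_size=64, epochs=10, learning_rate=0.02,
                           weight_decay=1e-3, warmup_epochs=2,
                           cooldown_epochs=4, seed=seed)


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    final_digest: str = ""


def cross_entropy(probabilities: np.ndarray, true_labels: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Mean negative log-probability of the true class.

    Probabilities are clamped at ``eps`` so a (mis)confident 0 does not
    produce an infinite loss.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(true_labels, dtype=np.int64)
    if p.ndim == 1:
        p = p[None, :]
        y = np.atleast_1d(y)
    picked = np.clip(p[np.arange(len(y)), y], eps, 1.0)
    return float(-np.mean(np.log(picked)))


def softmax_cross_entropy_grad(logits: np.ndarray,
                               true_labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically safe loss and d(loss)/d(logits) for a batch."""
    z = logits - logits.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(true_labels)
    loss = float(-log_probs[np.arange(n), true_labels].mean())
    grad = np.exp(log_probs)
    grad[np.arange(n), true_labels] -= 1.0
    return loss, grad / n


class SGD:
    """Stochastic gradient descent with classical momentum:
    v <- mu*v + g; p <- p - lr*v."""

    def __init__(self, params: list[nn.Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v


def parameter_digest(model) -> str:
    """SHA-256 over all parameter arrays, for reproducibility audits."""
    h = hashlib.sha256()
    for p in model.parameters():
        h.update(np.ascontiguousarray(p.value, dtype=np.float64).tobytes())
    return h.hexdigest()


def train(model, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig) -> TrainHistory:
    """Train ``model`` in place on the beat matrix ``X`` / labels ``y``.

    Per epoch: seeded shuffle, then one SGD update per mini-batch (the last
    short batch is kept).  The final ``cooldown_epochs`` run at a tenth of
    the learning rate.  Aborts with a diagnostic if the loss turns NaN.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(X) == 0:
        raise ValueError("training set is empty")
    if X.ndim != 2:
        raise ValueError("X must be (n_beats, beat_len)")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), cfg.learning_rate, cfg.momentum,
              cfg.weight_decay)
    history = TrainHistory()
    n = len(X)
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        if epoch < cfg.warmup_epochs:
            opt.lr = cfg.learning_rate / 10.0
        elif cfg.cooldown_epochs and epoch >= cfg.epochs - cfg.cooldown_epochs:
            opt.lr = cfg.learning_rate / 10.0
        else:
            opt.lr = cfg.learning_rate
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(X[idx], training=True)
            loss, grad = softmax_cross_entropy_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss in epoch {epoch}, batch at offset "
                    f"{start}; try a lower learning rate")
            model.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history.epoch_loss.append(float(np.sum(losses) / n))
        history.epoch_accuracy.append(correct / n)
        history.epoch_seconds.append(time.perf_counter() - t0)
    history.final_digest = parameter_digest(model)
    return history
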