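"""Adam optimizer and the training loop shared by the deep classifiers."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from . import ops

__all__ = ["Adam", "fit_classifier", "predict_proba"]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def fit_classifier(model, X: np.ndarray, y: np.ndarray, *, epochs: int = 50,
                   batch_size: int = 64, lr: float = 1e-3, patience: int = 10,
                   val_fraction: float = 0.1, seed: int = 0,
                   clip_norm: float = 5.0, augment=None) -> list[dict]:
    """Train ``model`` (forward(X, rng, training) -> logits) with Adam.

    Cross-entropy loss, gradient-norm clipping, early stopping on a held-out
    validation split (best parameters restored).  ``augment``, if given, is
    a callable ``(batch, rng) -> batch`` applied to every training batch
    (never to validation data).  Returns the per-epoch history of
    train/validation loss and accuracy.
    """
    rng = np.random.default_rng(seed)
    n = len(X)
    n_val = max(1, int(round(val_fraction * n))) if n >= 10 else 0
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xt, yt = X[train_idx], y[train_idx]
    Xv, yv = X[val_idx], y[val_idx]

    opt = Adam(model.params(), lr=lr)
    history: list[dict] = []
    best_loss, best_state, wait = np.inf, None, 0
    for epoch in range(epochs):
        losses, hits, count = [], 0, 0
        for idx in _batches(len(Xt), batch_size, rng):
            xb, yb = Xt[idx], yt[idx]
            if augment is not None:
                xb = augment(xb, rng)
            opt.zero_grad()
            logits = model.forward(Tensor(xb), rng, training=True)
            loss = ops.softmax_cross_entropy(logits, yb)
            loss.backward()
            _clip_gradients(opt.params, clip_norm)
            opt.step()
            losses.append(float(loss.data))
            hits += int(np.sum(np.argmax(logits.data, axis=1) == yb))
            count += len(yb)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "train_accuracy": hits / max(count, 1)}
        if n_val:
            pv = predict_proba(model, Xv)
            val_loss = float(-np.mean(np.log(
                pv[np.arange(len(yv)), yv] + 1e-12)))
            entry["val_loss"] = val_loss
            entry["val_accuracy"] = float(np.mean(np.argmax(pv, axis=1) == yv))
            if val_loss < best_loss - 1e-6:
                best_loss, wait = val_loss, 0
                best_state = [p.data.copy() for p in opt.params]
            else:
                wait += 1
        history.append(entry)
        if n_val and wait >= patience:
            break
    if best_state is not None:
        for p, s in zip(opt.params, best_state):
            p.data = s
    return history


def _clip_gradients(params: list[Tensor], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in params
                        if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def predict_proba(model, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Class probabilities without dropout or gradient tracking."""
    rng = np.random.default_rng(0)  # unused when training=False
    chunks = []
    for i in range(0, len(X), batch_size):
        logits = model.forward(Tensor(X[i:i + batch_size]), rng,
                               training=False)
        chunks.append(ops.softmax(logits.data))
    return np.concatenate(chunks, axis=0)
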