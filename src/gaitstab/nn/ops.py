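"""Differentiable operations on :class:`~gaitstab.nn.autodiff.Tensor`."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, astensor

__all__ = [
    "add", "sub", "mul", "neg", "matmul", "sigmoid", "tanh", "relu",
    "concat", "reshape", "transpose", "select_time", "stack_time",
    "dropout", "conv1d", "softmax_cross_entropy", "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))
    out.backward_fn = bw
    return out


def neg(a) -> Tensor:
    a = astensor(a)
    out = Tensor(-a.data, (a,))
    out.backward_fn = lambda g: a.accumulate(-g)
    return out


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))
    out.backward_fn = bw
    return out


def matmul(a, b) -> Tensor:
    """2-D matrix product (B, D) @ (D, H)."""
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)
    out.backward_fn = bw
    return out


def sigmoid(a) -> Tensor:
    a = astensor(a)
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out = Tensor(y, (a,))
    out.backward_fn = lambda g: a.accumulate(g * y * (1.0 - y))
    return out


def tanh(a) -> Tensor:
    a = astensor(a)
    y = np.tanh(a.data)
    out = Tensor(y, (a,))
    out.backward_fn = lambda g: a.accumulate(g * (1.0 - y * y))
    return out


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out.backward_fn = lambda g: a.accumulate(g * mask)
    return out


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(o0, o1)
            t.accumulate(g[tuple(sl)])
    out.backward_fn = bw
    return out


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out = Tensor(a.data.reshape(shape), (a,))
    out.backward_fn = lambda g: a.accumulate(g.reshape(a.data.shape))
    return out


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    out = Tensor(np.transpose(a.data, axes), (a,))
    inv = np.argsort(axes)
    out.backward_fn = lambda g: a.accumulate(np.transpose(g, inv))
    return out


def select_time(a, t: int) -> Tensor:
    """Pick timestep ``t`` from a (B, T, D) tensor -> (B, D)."""
    a = astensor(a)
    out = Tensor(a.data[:, t, :], (a,))

    def bw(g):
        full = np.zeros_like(a.data)
        full[:, t, :] = g
        a.accumulate(full)
    out.backward_fn = bw
    return out


def mean_time(a) -> Tensor:
    """Average a (B, T, D) tensor over its time axis -> (B, D)."""
    a = astensor(a)
    T = a.data.shape[1]
    out = Tensor(a.data.mean(axis=1), (a,))

    def bw(g):
        a.accumulate(np.repeat(g[:, None, :], T, axis=1) / T)
    out.backward_fn = bw
    return out


def stack_time(steps: list[Tensor]) -> Tensor:
    """Stack T tensors of shape (B, D) into (B, T, D)."""
    return concat([reshape(h, (h.shape[0], 1, h.shape[1])) for h in steps],
                  axis=1)


def dropout(a, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    a = astensor(a)
    if not training or p <= 0:
        return a
    mask = ((rng.random(a.data.shape) >= p) / (1.0 - p)).astype(a.data.dtype)
    out = Tensor(a.data * mask, (a,))
    out.backward_fn = lambda g: a.accumulate(g * mask)
    return out


def conv1d(x, w, b, stride: int = 1,
           pad: tuple[int, int] = (0, 0)) -> Tensor:
    """1-D convolution: x (B, C, L), w (F, C, K), b (F,) -> (B, F, L_out).

    Implemented as one im2col GEMM per direction for speed on CPU.
    """
    x, w, b = astensor(x), astensor(w), astensor(b)
    B, C, L = x.data.shape
    F, _, K = w.data.shape
    pl, pr = pad
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    out_len = (L + pl + pr - K) // stride + 1
    s0, s1, s2 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, K, out_len), strides=(s0, s1, s2, s2 * stride))
    # (C*K, B*out_len) column matrix; one contiguous copy
    col2 = np.ascontiguousarray(cols.transpose(1, 2, 0, 3)).reshape(
        C * K, B * out_len)
    wm = w.data.reshape(F, C * K)
    y = (wm @ col2).reshape(F, B, out_len).transpose(1, 0, 2)
    y = y + b.data[None, :, None]
    out = Tensor(np.ascontiguousarray(y), (x, w, b))

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2)).reshape(
            F, B * out_len)
        w.accumulate((g2 @ col2.T).reshape(F, C, K))
        gcols = (wm.T @ g2).reshape(C, K, B, out_len).transpose(2, 0, 1, 3)
        gxp = np.zeros_like(xp)
        for i in range(K):
            gxp[:, :, i:i + stride * out_len:stride] += gcols[:, :, i, :]
        x.accumulate(gxp[:, :, pl:pl + L])
        b.accumulate(g.sum(axis=(0, 2)))
    out.backward_fn = bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain NumPy softmax over the last axis (for prediction)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels ``y`` under softmax(logits)."""
    logits = astensor(logits)
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), y] + eps))
    out = Tensor(np.asarray(loss), (logits,))

    def bw(g):
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        logits.accumulate(g * grad / n)
    out.backward_fn = bw
    return out
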