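"""Layers for the sequence classifiers (dense, conv, GRU, LSTM, dropout)."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from . import ops

__all__ = ["Module", "Dense", "Conv1d", "GRU", "LSTM", "Dropout"]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base: tracks parameter tensors of this layer and sublayers."""

    def params(self) -> list[Tensor]:
        found: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor):
                found.append(value)
            elif isinstance(value, Module):
                found.extend(value.params())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        found.extend(item.params())
                    elif isinstance(item, Tensor):
                        found.append(item)
        return found


class Dense(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.w = Tensor(_glorot(rng, (d_in, d_out)), name="dense.w")
        self.b = Tensor(np.zeros(d_out), name="dense.b")

    def __call__(self, x: Tensor) -> Tensor:
        return ops.add(ops.matmul(x, self.w), self.b)


class Conv1d(Module):
    """Strided 1-D convolution with 'same'-style (ceil) output length."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int, stride: int = 1):
        scale = np.sqrt(6.0 / (c_in * kernel + c_out))
        self.w = Tensor(rng.uniform(-scale, scale, size=(c_out, c_in, kernel)),
                        name="conv.w")
        self.b = Tensor(np.zeros(c_out), name="conv.b")
        self.kernel = kernel
        self.stride = stride

    def out_len(self, length: int) -> int:
        return -(-length // self.stride)  # ceil division

    def __call__(self, x: Tensor) -> Tensor:
        length = x.shape[2]
        out_len = self.out_len(length)
        pad_total = max(0, (out_len - 1) * self.stride + self.kernel - length)
        pad = (pad_total // 2, pad_total - pad_total // 2)
        return ops.conv1d(x, self.w, self.b, stride=self.stride, pad=pad)


class GRU(Module):
    """Gated recurrent unit layer; consumes (B, T, D), returns (B, T, H)."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.hidden = hidden
        self.wz = Tensor(_glorot(rng, (d_in, hidden)))
        self.uz = Tensor(_glorot(rng, (hidden, hidden)))
        # positive update-gate bias: the unit initially tracks its input
        # (h ~ tanh(x W)), which conditions gradient flow through stacks
        self.bz = Tensor(np.full(hidden, 2.0))
        self.wr = Tensor(_glorot(rng, (d_in, hidden)))
        self.ur = Tensor(_glorot(rng, (hidden, hidden)))
        self.br = Tensor(np.zeros(hidden))
        self.wh = Tensor(_glorot(rng, (d_in, hidden)))
        self.uh = Tensor(_glorot(rng, (hidden, hidden)))
        self.bh = Tensor(np.zeros(hidden))

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden), dtype=x.data.dtype))
        one = Tensor(np.ones(1, dtype=x.data.dtype))
        outs = []
        for t in range(T):
            xt = ops.select_time(x, t)
            z = ops.sigmoid(ops.add(ops.add(ops.matmul(xt, self.wz),
                                            ops.matmul(h, self.uz)), self.bz))
            r = ops.sigmoid(ops.add(ops.add(ops.matmul(xt, self.wr),
                                            ops.matmul(h, self.ur)), self.br))
            hh = ops.tanh(ops.add(ops.add(ops.matmul(xt, self.wh),
                                          ops.matmul(ops.mul(r, h), self.uh)),
                                  self.bh))
            h = ops.add(ops.mul(ops.sub(one, z), h), ops.mul(z, hh))
            outs.append(h)
        return ops.stack_time(outs)


class LSTM(Module):
    """LSTM layer; consumes (B, T, D), returns (B, T, H)."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.hidden = hidden
        self.w = Tensor(_glorot(rng, (d_in, 4 * hidden)))
        self.u = Tensor(_glorot(rng, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H), dtype=x.data.dtype))
        c = Tensor(np.zeros((B, H), dtype=x.data.dtype))
        outs = []
        for t in range(T):
            xt = ops.select_time(x, t)
            gates = ops.add(ops.add(ops.matmul(xt, self.w),
                                    ops.matmul(h, self.u)), self.b)
            i = ops.sigmoid(_slice_cols(gates, 0, H))
            f = ops.sigmoid(_slice_cols(gates, H, 2 * H))
            g = ops.tanh(_slice_cols(gates, 2 * H, 3 * H))
            o = ops.sigmoid(_slice_cols(gates, 3 * H, 4 * H))
            c = ops.add(ops.mul(f, c), ops.mul(i, g))
            h = ops.mul(o, ops.tanh(c))
            outs.append(h)
        return ops.stack_time(outs)


def _slice_cols(x: Tensor, a: int, b: int) -> Tensor:
    out = Tensor(x.data[:, a:b], (x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[:, a:b] = g
        x.accumulate(full)
    out.backward_fn = bw
    return out


class Dropout(Module):
    def __init__(self, p: float):
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator,
                 training: bool) -> Tensor:
        return ops.dropout(x, self.p, rng, training)
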