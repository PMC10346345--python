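"""A small reverse-mode automatic differentiation engine on NumPy arrays.

Only what the sequence classifiers need: elementwise arithmetic with
broadcasting, 2-D matmul, sigmoid/tanh/relu, concatenation, reshape,
transpose, time-axis slicing, 1-D strided convolution and a fused
softmax-cross-entropy loss.  Gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "name")

    def __init__(self, data, parents=(), backward_fn=None, name=""):
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(
            data, np.ndarray) else data
        self.grad: np.ndarray | None = None
        self.parents: tuple["Tensor", ...] = parents
        self.backward_fn = backward_fn
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    # convenience operators (defined in ops to avoid circular imports)
    def __add__(self, other):
        from . import ops
        return ops.add(self, other)

    def __mul__(self, other):
        from . import ops
        return ops.mul(self, other)

    def __sub__(self, other):
        from . import ops
        return ops.sub(self, other)

    def __matmul__(self, other):
        from . import ops
        return ops.matmul(self, other)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, name={self.name!r})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))
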