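"""Reverse-mode automatic differentiation over NumPy arrays.

A ``Var`` wraps an ndarray and remembers how it was produced; calling
:func:`backward` on a scalar ``Var`` walks the recorded graph in reverse
topological order and accumulates gradients into every reachable node that
needs one.  The engine is deliberately small: only the operations required
by the segmentation network exist (see :mod:`mfuseg.nn.ops`), everything is
float64 by default, and there is no broadcasting cleverness beyond what the
individual ops implement.

Gradient bookkeeping rule: a node receives a gradient iff it has
``requires_grad`` set (trainable parameters) or was itself produced by an
op (interior nodes).  Plain data wrapped with ``requires_grad=False`` acts
as a constant leaf and its gradient is never materialised.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable

import numpy as np

_GRAD_STACK: list[bool] = [True]


def grad_enabled() -> bool:
    return _GRAD_STACK[-1]


@contextmanager
def no_grad():
    """Disable graph recording inside the block (inference / evaluation)."""
    _GRAD_STACK.append(False)
    try:
        yield
    finally:
        _GRAD_STACK.pop()


class Var:
    """A node in the computation graph: an array plus provenance."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(
        self,
        data,
        parents: Iterable["Var"] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        if grad_enabled():
            self.parents = tuple(parents)
            self.backward_fn = backward_fn
        else:
            self.parents = ()
            self.backward_fn = None

    @property
    def shape(self):
        return self.data.shape

    def needs_grad(self) -> bool:
        """Whether a gradient must flow into this node."""
        return self.requires_grad or self.backward_fn is not None

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias an upstream buffer that is reused
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Var(shape={self.data.shape}, requires_grad={self.requires_grad})"


def backward(root: Var, grad: np.ndarray | None = None) -> None:
    """Backpropagate from ``root`` through the recorded graph.

    ``root`` is typically the scalar loss; ``grad`` defaults to 1.
    """
    if grad is None:
        grad = np.ones_like(root.data)
    # iterative DFS topological sort (graphs are deep for big networks)
    order: list[Var] = []
    visited: set[int] = set()
    stack: list[tuple[Var, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in visited:
                stack.append((p, False))
    root.accumulate(grad)
    for node in reversed(order):
        if node.backward_fn is not None and node.grad is not None:
            node.backward_fn(node.grad)


def as_var(x, requires_grad: bool = False) -> Var:
    return x if isinstance(x, Var) else Var(np.asarray(x), requires_grad=requires_grad)
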