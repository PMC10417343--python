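"""Minimal reverse-mode autodiff tensor.

A :class:`Tensor` wraps a NumPy array and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  The op vocabulary (in :mod:`grrdb.nn.functional`)
is deliberately small: exactly what a convolutional denoiser needs.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- array-ish accessors -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs overflow Python recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the graph so intermediate buffers can be collected
        for node in topo:
            if node is not self:
                node._parents = ()
                node._backward = None

    def accumulate_grad(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    # -- operator sugar (implemented in functional to avoid cycles) ---------
    def __add__(self, other):
        from . import functional as F

        return F.add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        from . import functional as F

        return F.mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        from . import functional as F

        return F.sub(self, other)

    def __neg__(self):
        from . import functional as F

        return F.mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


class Parameter(Tensor):
    """A tensor that an optimizer updates."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
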