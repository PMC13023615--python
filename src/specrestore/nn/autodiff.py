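"""Vectorized reverse-mode automatic differentiation on numpy arrays.

Only the operations the spectral U-Nets need are implemented; every op's
backward pass is checked against central finite differences in the tests.
Shapes follow the (batch, channels, length) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "conv1d",
    "concat",
    "upsample2",
    "crop1d",
    "mse_loss",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype != np.float32 and data.dtype != np.float64:
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Reverse-mode sweep seeded with d(self)/d(self) = 1."""
        if self.data.size != 1:
            raise ValueError("backward() must be called on a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth scales with net depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _make(data, parents, backward) -> Tensor:
    requires = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=requires,
                  parents=parents if requires else (),
                  backward=backward if requires else None)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add requires identical shapes")

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad)
        if b.requires_grad:
            b._accumulate(grad)

    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("mul requires identical shapes")

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * b.data)
        if b.requires_grad:
            b._accumulate(grad * a.data)

    return _make(a.data * b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * mask)

    return _make(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """1D cross-correlation: x (B, Cin, L), w (Cout, Cin, K), b (Cout,).

    Implemented as im2col + BLAS matmul for speed.
    """
    B, Cin, L = x.data.shape
    Cout, Cin_w, K = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    xpad = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    Lp = xpad.shape[2]
    Lout = (Lp - K) // stride + 1
    if Lout < 1:
        raise ValueError("kernel larger than padded input")
    view = sliding_window_view(xpad, K, axis=2)[:, :, ::stride, :]  # (B,Cin,Lout,K)
    # (B*Lout, Cin*K) @ (Cin*K, Cout)
    cols = np.ascontiguousarray(view.transpose(0, 2, 1, 3)).reshape(B * Lout, Cin * K)
    w_mat = w.data.reshape(Cout, Cin * K)
    out = (cols @ w_mat.T).reshape(B, Lout, Cout).transpose(0, 2, 1)
    out = np.ascontiguousarray(out)
    out += b.data[None, :, None]

    def backward(grad):
        # grad: (B, Cout, Lout)
        g_mat = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(B * Lout, Cout)
        if b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2)))
        if w.requires_grad:
            w._accumulate((g_mat.T @ cols).reshape(Cout, Cin, K))
        if x.requires_grad:
            # scatter (B*Lout, Cin*K) columns back onto the padded input
            gcols = (g_mat @ w_mat).reshape(B, Lout, Cin, K)
            gxpad = np.zeros_like(xpad)
            span = stride * (Lout - 1) + 1
            for k in range(K):
                gxpad[:, :, k : k + span : stride] += gcols[:, :, :, k].transpose(0, 2, 1)
            if padding:
                gxpad = gxpad[:, :, padding:-padding]
            x._accumulate(gxpad)

    return _make(out, (x, w, b), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    na = a.data.shape[1]

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad[:, :na])
        if b.requires_grad:
            b._accumulate(grad[:, na:])

    return _make(np.concatenate([a.data, b.data], axis=1), (a, b), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by 2 along the length axis."""

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad[:, :, 0::2] + grad[:, :, 1::2])

    return _make(np.repeat(x.data, 2, axis=2), (x,), backward)


def crop1d(x: Tensor, lo: int, hi: int) -> Tensor:
    """Slice [lo:hi] along the length axis."""
    L = x.data.shape[2]

    def backward(grad):
        if x.requires_grad:
            g = np.zeros_like(x.data)
            g[:, :, lo:hi] = grad
            x._accumulate(g)

    if not (0 <= lo < hi <= L):
        raise ValueError(f"invalid crop [{lo}:{hi}] for length {L}")
    return _make(x.data[:, :, lo:hi], (x,), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    target = np.asarray(target, dtype=pred.data.dtype)
    if target.shape != pred.data.shape:
        raise ValueError("target shape must match prediction shape")
    diff = pred.data - target
    n = diff.size

    def backward(grad):
        if pred.requires_grad:
            pred._accumulate((2.0 / n) * diff * grad)

    return _make(np.array(np.mean(diff * diff)), (pred,), backward)
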