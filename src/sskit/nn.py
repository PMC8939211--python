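"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just the operations a 1-D convolutional encoder–decoder needs: same-
padding conv1d, ReLU/sigmoid, max-pool and nearest-neighbour upsample by
factor 2, channel concatenation, broadcast add/multiply, dropout and a
masked softmax cross-entropy.  Gradients flow through a taped graph of
:class:`Tensor` nodes; :class:`Adam` updates the parameters.

Arrays are laid out as (batch, length, channels) throughout.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv1d",
    "relu",
    "sigmoid",
    "add",
    "mul",
    "concat",
    "maxpool2",
    "upsample2",
    "dropout",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Tensor:
    """A node in the computation graph: value, gradient, backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Tensor"] = (),
        requires_grad: bool = False,
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes numpy broadcasting expanded."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(a.data + b.data, (a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(a.data * b.data, (a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    pos = x.data > 0

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * pos)

    return Tensor(x.data * pos, (x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * y * (1.0 - y))

    return Tensor(y, (x,), backward=backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 1-D convolution.

    x: (B, L, C_in); w: (K, C_in, C_out); b: (C_out,).
    """
    batch, length, c_in = x.data.shape
    k, _, c_out = w.data.shape
    pad_l = k // 2
    pad_r = k - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    # (B, L, C_in, K) -> (B, L, K*C_in)
    patches = sliding_window_view(xp, k, axis=1).transpose(0, 1, 3, 2)
    patches = np.ascontiguousarray(patches).reshape(batch, length, k * c_in)
    w_flat = w.data.reshape(k * c_in, c_out)
    y = patches @ w_flat + b.data

    def backward(g: np.ndarray) -> None:
        if w.requires_grad:
            dw = np.einsum("blp,blf->pf", patches, g)
            w.accumulate(dw.reshape(k, c_in, c_out))
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            dpatches = (g @ w_flat.T).reshape(batch, length, k, c_in)
            dxp = np.zeros_like(xp)
            for kk in range(k):
                dxp[:, kk : kk + length, :] += dpatches[:, :, kk, :]
            x.accumulate(dxp[:, pad_l : pad_l + length, :])

    return Tensor(y, (x, w, b), backward=backward)


def concat(tensors: Sequence[Tensor], axis: int = 2) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, bounds[:-1], bounds[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors),
        backward=backward,
    )


def maxpool2(x: Tensor) -> Tensor:
    """Max-pool pairs along the length axis (length must be even)."""
    batch, length, ch = x.data.shape
    if length % 2:
        raise ValueError(f"maxpool2 needs an even length, got {length}")
    xr = x.data.reshape(batch, length // 2, 2, ch)
    idx = xr.argmax(axis=2)
    y = xr.max(axis=2)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dxr = np.zeros_like(xr)
            np.put_along_axis(dxr, idx[:, :, None, :], g[:, :, None, :], axis=2)
            x.accumulate(dxr.reshape(batch, length, ch))

    return Tensor(y, (x,), backward=backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by 2 along the length axis."""
    batch, length, ch = x.data.shape
    y = np.repeat(x.data, 2, axis=1)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g.reshape(batch, length, 2, ch).sum(axis=2))

    return Tensor(y, (x,), backward=backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(x.data * mask, (x,), backward=backward)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain (non-taped) softmax for inference outputs."""
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: Tensor, targets: np.ndarray, mask: np.ndarray
) -> Tensor:
    """Mean masked categorical cross-entropy over real (unpadded) positions.

    logits: (B, L, K); targets: one-hot (B, L, K); mask: (B, L) with 1
    on residues that count.
    """
    p = softmax(logits.data, axis=2)
    n = mask.sum()
    if n == 0:
        raise ValueError("empty mask in cross-entropy")
    logp = np.log(np.clip(p, 1e-12, None))
    loss = -(mask[:, :, None] * targets * logp).sum() / n

    def backward(g: np.ndarray) -> None:
        if logits.requires_grad:
            logits.accumulate(g * mask[:, :, None] * (p - targets) / n)

    return Tensor(np.asarray(loss), (logits,), backward=backward)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
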