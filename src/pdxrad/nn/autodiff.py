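"""Minimal reverse-mode automatic differentiation on numpy arrays.

Tensors form a DAG; ``backward(loss)`` topologically sorts it and runs each
node's gradient closure.  Activations use the NHWC layout
``(batch, height, width, channel)``; convolution weights are
``(kh, kw, c_in, c_out)``.  Weight sharing (e.g. a recurrent convolution
applied twice) works out of the box because gradients accumulate.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "xavier_init",
    "conv2d",
    "maxpool2",
    "upsample2",
    "relu",
    "sigmoid",
    "add",
    "concat",
    "mul_const",
    "dice_loss_op",
    "backward",
    "release",
]


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None


def xavier_init(shape: Sequence[int], rng: np.random.Generator) -> Tensor:
    """Glorot-uniform parameter tensor; fans from the conv weight layout."""
    shape = tuple(shape)
    if len(shape) == 4:  # (kh, kw, cin, cout)
        receptive = shape[0] * shape[1]
        fan_in, fan_out = receptive * shape[2], receptive * shape[3]
    else:
        fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 2-D convolution (odd square kernels)."""
    n, h, wd, cin = x.data.shape
    k = w.data.shape[0]
    cout = w.data.shape[3]
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.data
    out = np.zeros((n * h * wd, cout))
    for di in range(k):
        for dj in range(k):
            patch = xp[:, di : di + h, dj : dj + wd, :].reshape(-1, cin)
            out += patch @ w.data[di, dj]
    out += b.data
    res = Tensor(out.reshape(n, h, wd, cout), (x, w, b))

    def bwd() -> None:
        g = res.grad.reshape(-1, cout)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                if w.requires_grad:
                    patch = xp[:, di : di + h, dj : dj + wd, :].reshape(-1, cin)
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[di, dj] += patch.T @ g
                if x.requires_grad:
                    gxp[:, di : di + h, dj : dj + wd, :] += (
                        g @ w.data[di, dj].T
                    ).reshape(n, h, wd, cin)
        if x.requires_grad:
            x.accum(gxp[:, pad : pad + h, pad : pad + wd, :] if pad else gxp)
        b.accum(res.grad.sum(axis=(0, 1, 2)))

    res.backward_fn = bwd
    return res


def maxpool2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    h2, w2 = h // 2, w // 2
    r = (
        x.data.reshape(n, h2, 2, w2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h2, w2, c, 4)
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    res = Tensor(out, (x,))

    def bwd() -> None:
        z = np.zeros((n, h2, w2, c, 4))
        np.put_along_axis(z, idx[..., None], res.grad[..., None], axis=-1)
        x.accum(
            z.reshape(n, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )

    res.backward_fn = bwd
    return res


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial up-sampling."""
    n, h, w, c = x.data.shape
    res = Tensor(x.data.repeat(2, axis=1).repeat(2, axis=2), (x,))

    def bwd() -> None:
        x.accum(res.grad.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))

    res.backward_fn = bwd
    return res


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    res = Tensor(x.data * mask, (x,))
    res.backward_fn = lambda: x.accum(res.grad * mask)
    return res


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    res = Tensor(s, (x,))
    res.backward_fn = lambda: x.accum(res.grad * s * (1.0 - s))
    return res


def add(a: Tensor, b: Tensor) -> Tensor:
    res = Tensor(a.data + b.data, (a, b))

    def bwd() -> None:
        a.accum(res.grad)
        b.accum(res.grad)

    res.backward_fn = bwd
    return res


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    res = Tensor(np.concatenate([t.data for t in tensors], axis=-1), tuple(tensors))
    splits = np.cumsum([t.data.shape[-1] for t in tensors])[:-1]

    def bwd() -> None:
        for t, g in zip(tensors, np.split(res.grad, splits, axis=-1)):
            t.accum(g)

    res.backward_fn = bwd
    return res


def mul_const(x: Tensor, const: np.ndarray) -> Tensor:
    """Multiply by a constant array (broadcastable); used for dropout masks."""
    res = Tensor(x.data * const, (x,))

    def bwd() -> None:
        g = res.grad * const
        # reduce broadcast axes back to x's shape
        extra = g.ndim - x.data.ndim
        if extra:
            g = g.sum(axis=tuple(range(extra)))
        for ax, (gs, xs) in enumerate(zip(g.shape, x.data.shape)):
            if xs == 1 and gs != 1:
                g = g.sum(axis=ax, keepdims=True)
        x.accum(g)

    res.backward_fn = bwd
    return res


def dice_loss_op(pred: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss 1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps).

    Sums run over the whole batch; ``eps`` keeps empty-mask batches finite.
    """
    t = np.asarray(target, dtype=np.float64)
    if t.shape != pred.data.shape:
        raise ValueError("pred and target shapes differ")
    num = 2.0 * float((pred.data * t).sum()) + eps
    den = float(pred.data.sum() + t.sum()) + eps
    res = Tensor(np.asarray(1.0 - num / den), (pred,))

    def bwd() -> None:
        # d/dp of -(num/den) = -(2t*den - num)/den^2
        pred.accum(res.grad * (-(2.0 * t * den - num) / den**2))

    res.backward_fn = bwd
    return res


def backward(loss: Tensor, release_graph: bool = True) -> None:
    """Run reverse-mode differentiation from a scalar loss.

    With ``release_graph`` (default) the graph's closures and parent links
    are dropped afterwards, breaking the tensor<->closure reference cycles
    so large intermediate arrays are freed immediately rather than waiting
    for the cyclic garbage collector.  Parameter gradients are preserved.
    """
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in visited and p.requires_grad:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node.backward_fn is not None and node.grad is not None:
            node.backward_fn()
    if release_graph:
        for node in topo:
            node.backward_fn = None
            node.parents = ()


def release(t: Tensor) -> None:
    """Break the reference cycles of a forward graph that will not be
    differentiated (e.g. inference passes)."""
    stack = [t]
    seen: set[int] = set()
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.extend(node.parents)
        node.backward_fn = None
        node.parents = ()
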