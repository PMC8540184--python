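"""Minimal reverse-mode autodiff on numpy arrays.

Only the handful of dense-prediction ops the segmentation networks need
are provided (stride-1 conv, 2x2 maxpool, 2x2-stride-2 transposed conv,
batchnorm, relu/sigmoid, concat, add).  Everything runs in float32 NCHW.
Gradients are only propagated into tensors that require them, so input
images cost no backward work.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "relu",
    "sigmoid",
    "add",
    "concat",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this node (defaults to a ones seed)."""
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
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float32)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * (x.data > 0))

    return Tensor(out_data, _parents=(x,), _backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, _parents=(x,), _backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return Tensor(out_data, _parents=(a, b), _backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t.accumulate(np.take(g, range(lo, hi), axis=axis))

    return Tensor(out_data, _parents=tuple(tensors), _backward=backward)


def _im2col(xp: np.ndarray, kh: int, kw: int, oh: int, ow: int) -> np.ndarray:
    """(N, C*kh*kw, oh*ow) patch matrix of a padded NCHW input."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + oh, j : j + ow]
    return cols.reshape(n, c * kh * kw, oh * ow)


def conv2d(x: Tensor, w: Tensor, pad: int) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), NCHW x (OC, C, KH, KW)."""
    n, c, h, wd = x.data.shape
    oc, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    oh, ow = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    cols = _im2col(xp, kh, kw, oh, ow)
    wmat = w.data.reshape(oc, c * kh * kw)
    out_data = np.matmul(wmat[None], cols).reshape(n, oc, oh, ow)

    def backward(g):
        g2 = g.reshape(n, oc, oh * ow)
        if w.requires_grad:
            gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w.accumulate(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T[None], g2).reshape(n, c, kh, kw, oh, ow)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + oh, j : j + ow] += gcols[:, :, i, j]
            x.accumulate(gxp[:, :, pad : pad + h, pad : pad + wd] if pad else gxp)

    return Tensor(out_data, _parents=(x, w), _backward=backward)


def conv_transpose2x2(x: Tensor, w: Tensor) -> Tensor:
    """Transposed conv, kernel 2 stride 2: each input pixel emits a 2x2 block."""
    n, c, h, wd = x.data.shape
    cin, oc = w.data.shape[:2]
    if cin != c:
        raise ValueError(f"conv_transpose channel mismatch: input has {c}, kernel expects {cin}")
    out6 = np.einsum("nchw,coab->nohawb", x.data, w.data, optimize=True)
    out_data = out6.reshape(n, oc, 2 * h, 2 * wd)

    def backward(g):
        g6 = g.reshape(n, oc, h, 2, wd, 2)
        if w.requires_grad:
            w.accumulate(np.einsum("nohawb,nchw->coab", g6, x.data, optimize=True))
        if x.requires_grad:
            x.accumulate(np.einsum("nohawb,coab->nchw", g6, w.data, optimize=True))

    return Tensor(out_data, _parents=(x, w), _backward=backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling; spatial sides must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial sides, got {h}x{w}")
    xw = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xw = xw.reshape(n, c, h // 2, w // 2, 4)
    idx = xw.argmax(axis=-1)
    out_data = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gxw = np.zeros_like(xw)
            np.put_along_axis(gxw, idx[..., None], g[..., None], axis=-1)
            gx = gxw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x.accumulate(gx.reshape(n, c, h, w))

    return Tensor(out_data, _parents=(x,), _backward=backward)
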