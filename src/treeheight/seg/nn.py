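"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations a small encoder-decoder segmentation
network needs: 2-D convolution (stride 1, via im2col/col2im), 2x2 max
pooling, 2x nearest-neighbor upsampling, ReLU, sigmoid, elementwise add and
(broadcasting) multiply, channel concatenation, and a mean binary
cross-entropy-with-logits loss — plus an Adam optimizer.

Tensors are NCHW float64 by default; gradients flow through a topologically
sorted tape.  This is deliberately small and CPU-only: the networks trained
here are desk-scale.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Sequence["Tensor"] = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._prev = tuple(_prev)
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Reverse pass from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._prev for t in tensors)


def _node(data, parents, backward) -> Tensor:
    if _needs(*parents):
        return Tensor(data, _prev=parents, _backward=backward)
    return Tensor(data)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that numpy broadcasting expanded."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _node(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return _node(s, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _node(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution


def _im2col(xp: np.ndarray, k: int, H: int, W: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C*k*k, H*W) patch matrix."""
    N, C = xp.shape[:2]
    cols = np.empty((N, C, k, k, H, W), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki, kj] = xp[:, :, ki:ki + H, kj:kj + W]
    return cols.reshape(N, C * k * k, H * W)


def _col2im(gcols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back to the padded image."""
    N, C, H, W = shape
    g = gcols.reshape(N, C, k, k, H, W)
    gxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=gcols.dtype)
    for ki in range(k):
        for kj in range(k):
            gxp[:, :, ki:ki + H, kj:kj + W] += g[:, :, ki, kj]
    return gxp[:, :, pad:pad + H, pad:pad + W] if pad else gxp


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: Optional[int] = None) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), 'same' padding by default.

    x: (N, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,).
    """
    N, Cin, H, W = x.data.shape
    Cout, Cin_w, k, _ = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"conv2d channel mismatch: {Cin} vs {Cin_w}")
    if pad is None:
        pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    Ho, Wo = H + 2 * pad - k + 1, W + 2 * pad - k + 1
    cols = _im2col(xp, k, Ho, Wo)
    w2 = w.data.reshape(Cout, Cin * k * k)
    out = np.matmul(w2[None], cols) + b.data.reshape(1, Cout, 1)
    out_data = out.reshape(N, Cout, Ho, Wo)

    def backward(g):
        g2 = g.reshape(N, Cout, Ho * Wo)
        w._accumulate(np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
                      .reshape(w.data.shape))
        b._accumulate(g2.sum(axis=(0, 2)))
        gcols = np.matmul(w2.T[None], g2)
        x._accumulate(_col2im(gcols.reshape(N, Cin, k, k, Ho, Wo)
                              .reshape(N, Cin * k * k, Ho * Wo),
                              (N, Cin, Ho, Wo), k, pad))

    return _node(out_data, (x, w, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 needs even spatial dims")
    xr = (x.data.reshape(N, C, H // 2, 2, W // 2, 2)
          .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4))
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((N, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (gr.reshape(N, C, H // 2, W // 2, 2, 2)
              .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W))
        x._accumulate(gx)

    return _node(out_data, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        N, C, H2, W2 = g.shape
        x._accumulate(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    return _node(out_data, (x,), backward)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel binary cross-entropy on raw scores (numerically stable)."""
    t = np.asarray(target, dtype=np.float64)
    z = logits.data
    # log(1 + exp(-|z|)) formulation
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out_data = np.array(loss.mean())

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        logits._accumulate(g * (s - t) / z.size)

    return _node(out_data, (logits,), backward)


# ---------------------------------------------------------------------------
# parameters and optimization


def he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    """Kaiming-normal weight tensor (suits ReLU nonlinearities)."""
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return Tensor(w, requires_grad=True)


def zeros_param(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class Adam:
    """Standard Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
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
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
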