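"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied to
it; :meth:`Tensor.backward` accumulates gradients by reverse topological
traversal.  The op set is exactly what the models in this package need
(elementwise arithmetic with broadcasting, matmul, strided 2-D convolution,
common nonlinearities, reductions, reshaping, concatenation and masked
selection) — it is not a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "concatenate", "where", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, prev, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        grad = grad.astype(np.float32, copy=False)
        self.grad = grad if self.grad is None else self.grad + grad

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        # log(1 + e^x) = max(x, 0) + log1p(e^-|x|), stable and ufunc-cheap
        x = self.data
        out_data = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        sig = _sigmoid(x)

        def backward(g):
            self._accum(g * sig)

        return self._make(out_data, (self,), backward)

    def log_sigmoid(self):
        return -((-self).softplus())

    def clip_min(self, lo: float):
        mask = self.data > lo
        out_data = np.maximum(self.data, lo)

        def backward(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        # basic indexing (ints/slices) never repeats elements, so a plain
        # in-place add is valid and much faster than np.add.at
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, np.integer, slice, type(None),
                                   type(Ellipsis))) for p in parts)

        def backward(g):
            full = np.zeros_like(self.data)
            if basic:
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def concatenate(tensors, axis=-1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(t for t in tensors if t.requires_grad)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        out._backward = backward
    return out


def where(cond: np.ndarray, a, b) -> Tensor:
    """Select elementwise by a boolean ndarray `cond` (not differentiated)."""
    a, b = _as_tensor(a), _as_tensor(b)
    cond = np.asarray(cond, dtype=bool)
    out_data = np.where(cond, a.data, b.data)

    out = Tensor(out_data)
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._prev = tuple(t for t in (a, b) if t.requires_grad)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(np.where(cond, g, 0.0), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.where(cond, 0.0, g), b.data.shape))

        out._backward = backward
    return out


def logsumexp(x: Tensor, axis: int) -> Tensor:
    """Stable log-sum-exp reduction along `axis`."""
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)
    return shifted.exp().sum(axis=axis) .log() + Tensor(np.squeeze(m, axis=axis))


def _extract_patches(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B,H,W,C) -> (B,Ho,Wo,kh,kw,C) view via stride tricks."""
    b, h, w, c = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sb, sh, sw, sc = x.strides
    shape = (b, ho, wo, kh, kw, c)
    strides = (sb, sh * stride, sw * stride, sh, sw, sc)
    return np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1,
           padding: int = 0, mask: np.ndarray | None = None) -> Tensor:
    """2-D convolution (cross-correlation), NHWC layout.

    `weight` has shape (kh, kw, Cin, Cout).  `mask`, if given, is a fixed
    binary array broadcastable to the weight shape; it is applied
    multiplicatively at every use, which implements the autoregressive
    raster-order masking of the pixel stream.
    """
    kh, kw, cin, cout = weight.shape
    w_eff = weight.data if mask is None else weight.data * mask
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    patches = _extract_patches(xd, kh, kw, stride)
    b, ho, wo = patches.shape[:3]
    cols = patches.reshape(b * ho * wo, kh * kw * cin)
    out_data = cols @ w_eff.reshape(kh * kw * cin, cout)
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.reshape(b, ho, wo, cout)

    out = Tensor(out_data)
    prev = [t for t in (x, weight, bias) if t is not None and t.requires_grad]
    if prev:
        out.requires_grad = True
        out._prev = tuple(prev)
        cols_saved = cols if weight.requires_grad else None

        def backward(g):
            g2 = g.reshape(b * ho * wo, cout)
            if weight.requires_grad:
                gw = (cols_saved.T @ g2).reshape(kh, kw, cin, cout)
                if mask is not None:
                    gw = gw * mask
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g2.sum(axis=0))
            if x.requires_grad:
                gcols = g2 @ w_eff.reshape(kh * kw * cin, cout).T
                gcols = gcols.reshape(b, ho, wo, kh, kw, cin)
                hp, wp = xd.shape[1], xd.shape[2]
                gx = np.zeros((b, hp, wp, cin), dtype=np.float32)
                # scatter-add per kernel offset (kh*kw slice adds)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, i : i + ho * stride : stride,
                           j : j + wo * stride : stride, :] += gcols[:, :, :, i, j, :]
                if padding:
                    gx = gx[:, padding:-padding, padding:-padding, :]
                x._accum(gx)

        out._backward = backward
    return out
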