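"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-based engine in the spirit of the classic define-by-run frameworks,
providing exactly the primitives the networks in this package need: dense
algebra, the usual activations, layer normalisation, embedding lookup, 1-D
(transposed) convolution and masked softmax.  Every primitive's gradient is
verified against central finite differences in the test suite.

The engine favours clarity over raw speed; the models here are small enough
(tens of thousands of parameters, short character sequences) that NumPy's
vectorised kernels carry the cost and the Python tape overhead stays minor.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "embedding",
    "layer_norm",
    "masked_softmax",
    "conv1d",
    "conv_transpose1d",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (evaluation / frozen nets)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64) + (
            self.grad if self.grad is not None else 0.0
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go
                node._backward = None
                node._parents = ()

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:

            def bwd(g):
                if self.requires_grad:
                    self._accumulate(g)
                if other.requires_grad:
                    other._accumulate(g)

            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:

            def bwd(g):
                if self.requires_grad:
                    self._accumulate(g * other.data)
                if other.requires_grad:
                    other._accumulate(g * self.data)

            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = _make(self.data / other.data, (self, other))
        if out._parents:

            def bwd(g):
                if self.requires_grad:
                    self._accumulate(g / other.data)
                if other.requires_grad:
                    other._accumulate(-g * self.data / other.data**2)

            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out = _make(self.data**exponent, (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:

            def bwd(g):
                a, b = self.data, other.data
                if self.requires_grad:
                    if b.ndim == 1:
                        ga = np.multiply.outer(g, b) if g.ndim else g * b
                    else:
                        ga = g @ np.swapaxes(b, -1, -2)
                    self._accumulate(_unbroadcast(ga, a.shape))
                if other.requires_grad:
                    if a.ndim == 1:
                        gb = np.multiply.outer(a, g) if g.ndim else a * g
                    else:
                        gb = np.swapaxes(a, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, b.shape))

            out._backward = bwd
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = _make(y, (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _make(y, (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * (1.0 - y**2))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(y, (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def leaky_relu(self, alpha: float = 0.2):
        out = _make(np.where(self.data > 0, self.data, alpha * self.data), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(
                g * np.where(self.data > 0, 1.0, alpha)
            )
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values to [lo, hi]; gradient passes only through the interior."""
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out._parents:
            inside = (self.data >= lo) & (self.data <= hi)
            out._backward = lambda g: self._accumulate(g * inside)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:

            def bwd(g):
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape))

            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first maximum."""
        y = self.data.max(axis=axis, keepdims=True)
        out_data = y if keepdims else np.squeeze(y, axis=axis)
        out = _make(out_data, (self,))
        if out._parents:
            hit = self.data == y
            first = np.cumsum(hit, axis=axis) == 1
            mask = hit & first

            def bwd(g):
                gg = np.asarray(g)
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.where(mask, gg, 0.0))

            out._backward = bwd
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(
                np.asarray(g).reshape(self.data.shape)
            )
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(
                np.asarray(g).transpose(tuple(inv))
            )
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._parents:

            def bwd(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

            out._backward = bwd
        return out


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    live = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if live:
        out.requires_grad = True
        out._parents = tuple(parents)
    return out


# -- compound / structural primitives -----------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = bwd
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather: out[..., :] = weight[ids[...], :]."""
    ids = np.asarray(ids, dtype=np.intp)
    out = _make(weight.data[ids], (weight,))
    if out._parents:

        def bwd(g):
            gw = np.zeros_like(weight.data)
            np.add.at(gw, ids, g)
            weight._accumulate(gw)

        out._backward = bwd
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then affine with `gain`/`bias`."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = _make(xhat * gain.data + bias.data, (x, gain, bias))
    if out._parents:
        d = x.data.shape[-1]

        def bwd(g):
            g = np.asarray(g)
            if gain.requires_grad:
                gain._accumulate((g * xhat).reshape(-1, d).sum(axis=0))
            if bias.requires_grad:
                bias._accumulate(g.reshape(-1, d).sum(axis=0))
            if x.requires_grad:
                dxhat = g * gain.data
                m1 = dxhat.mean(axis=-1, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
                x._accumulate(inv * (dxhat - m1 - xhat * m2))

        out._backward = bwd
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; positions where `mask` is False get weight 0.

    Raises if any row is entirely masked (degenerate softmax).
    """
    s = scores.data
    if mask is not None:
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), s.shape)
        if not mask.any(axis=-1).all():
            raise ValueError("softmax row with all positions masked")
        s = np.where(mask, s, -np.inf)
    m = np.max(s, axis=-1, keepdims=True)
    e = np.exp(s - m)
    if mask is not None:
        e = np.where(mask, e, 0.0)
    p = e / e.sum(axis=-1, keepdims=True)
    out = _make(p, (scores,))
    if out._parents:

        def bwd(g):
            g = np.asarray(g)
            dot = (g * p).sum(axis=-1, keepdims=True)
            ds = p * (g - dot)
            scores._accumulate(ds)

        out._backward = bwd
    return out


# -- 1-D convolution ----------------------------------------------------------


def _windows(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Sliding windows view of x (B, C, T) -> (B, C, T_out, K)."""
    b, c, t = x.shape
    t_out = (t - kernel) // stride + 1
    sb, sc, st = x.strides
    return np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, t_out, kernel),
        strides=(sb, sc, st * stride, st),
        writeable=False,
    )


def conv1d(
    x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0
) -> Tensor:
    """x: (B, C_in, T); weight: (C_out, C_in, K); bias: (C_out,)."""
    b, c_in, t = x.data.shape
    c_out, c_in2, k = weight.data.shape
    if c_in != c_in2:
        raise ValueError(f"conv1d channel mismatch: {c_in} vs {c_in2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    if xp.shape[-1] < k:
        raise ValueError("input shorter than kernel after padding")
    win = _windows(xp, k, stride)
    out_data = np.einsum("bctk,ock->bot", win, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[:, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _make(out_data, parents)
    if out._parents:
        t_out = win.shape[2]

        def bwd(g):
            g = np.asarray(g)
            if weight.requires_grad:
                weight._accumulate(np.einsum("bot,bctk->ock", g, win, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2)))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for kk in range(k):
                    sl = slice(kk, kk + stride * t_out, stride)
                    dxp[:, :, sl] += np.einsum(
                        "bot,oc->bct", g, weight.data[:, :, kk], optimize=True
                    )
                x._accumulate(dxp[:, :, padding : padding + t])

        out._backward = bwd
    return out


def conv_transpose1d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None,
    stride: int = 1,
    padding: int = 0,
    output_padding: int = 0,
) -> Tensor:
    """x: (B, C_in, T); weight: (C_in, C_out, K); output length (T-1)s - 2p + K + op."""
    b, c_in, t = x.data.shape
    c_in2, c_out, k = weight.data.shape
    if c_in != c_in2:
        raise ValueError(f"conv_transpose1d channel mismatch: {c_in} vs {c_in2}")
    t_full = (t - 1) * stride + k
    t_out = t_full - 2 * padding + output_padding
    if t_out <= 0:
        raise ValueError("non-positive output length")
    full = np.zeros((b, c_out, t_full))
    for kk in range(k):
        full[:, :, kk : kk + stride * t : stride] += np.einsum(
            "bct,co->bot", x.data, weight.data[:, :, kk], optimize=True
        )
    out_data = full[:, :, padding : padding + t_out]
    if t_out > t_full - padding:  # output_padding extends past the full map
        pad_extra = t_out - (t_full - padding)
        out_data = np.pad(full[:, :, padding:], ((0, 0), (0, 0), (0, pad_extra)))
    if bias is not None:
        out_data = out_data + bias.data[:, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _make(out_data, parents)
    if out._parents:

        def bwd(g):
            g = np.asarray(g)
            gfull = np.zeros((b, c_out, t_full))
            usable = min(t_out, t_full - padding)
            gfull[:, :, padding : padding + usable] = g[:, :, :usable]
            if weight.requires_grad or x.requires_grad:
                for kk in range(k):
                    piece = gfull[:, :, kk : kk + stride * t : stride]
                    if weight.requires_grad:
                        weight._accumulate(
                            np.pad(
                                np.einsum("bct,bot->co", x.data, piece, optimize=True)[
                                    :, :, None
                                ],
                                ((0, 0), (0, 0), (kk, k - kk - 1)),
                            )
                        )
                    if x.requires_grad:
                        x._accumulate(
                            np.einsum(
                                "bot,co->bct", piece, weight.data[:, :, kk], optimize=True
                            )
                        )
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2)))

        out._backward = bwd
    return out
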