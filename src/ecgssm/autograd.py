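"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the classifier needs: broadcasting
arithmetic, matmul, pointwise nonlinearities, reductions, reshaping, strided
1-D convolution and a fused selective-scan primitive whose backward pass is
hand-derived backpropagation through time.  Every primitive's gradient is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus a backward closure in a dynamically built graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph mechanics ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other, dtype=float))

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- arithmetic -----------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data
    return _make(data, (a, b), lambda g: (_unbroadcast(g, a.shape),
                                          _unbroadcast(g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data
    return _make(data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.shape),
                            _unbroadcast(g * a.data, b.shape)))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _make(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** exponent
    return _make(data, (a,),
                 lambda g: (g * exponent * a.data ** (exponent - 1),))


# -- pointwise nonlinearities ---------------------------------------------


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)
    return _make(data, (a,), lambda g: (g * data,))


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), lambda g: (g / a.data,))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 0.5 * (1 + np.tanh(0.5 * a.data))  # numerically stable
    return _make(data, (a,), lambda g: (g * data * (1 - data),))


def softplus(a) -> Tensor:
    """log(1 + exp(x)), computed stably for large |x|."""
    a = as_tensor(a)
    data = np.maximum(a.data, 0) + np.log1p(np.exp(-np.abs(a.data)))
    sig = 0.5 * (1 + np.tanh(0.5 * a.data))
    return _make(data, (a,), lambda g: (g * sig,))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return _make(a.data * mask, (a,), lambda g: (g * mask,))


# -- reductions and shaping -----------------------------------------------


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.shape).copy(),)

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.reshape(shape), (a,),
                 lambda g: (g.reshape(a.shape),))


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inverse = np.argsort(axes)
    return _make(a.data.transpose(axes), (a,),
                 lambda g: (g.transpose(inverse),))


def flip(a, axis: int) -> Tensor:
    a = as_tensor(a)
    return _make(np.flip(a.data, axis=axis), (a,),
                 lambda g: (np.flip(g, axis=axis),))


def pad_last(a, left: int, right: int) -> Tensor:
    """Zero-pad the last axis."""
    a = as_tensor(a)
    spec = [(0, 0)] * (a.data.ndim - 1) + [(left, right)]
    data = np.pad(a.data, spec)
    n = a.shape[-1]
    return _make(data, (a,), lambda g: (g[..., left:left + n],))


# -- convolution ----------------------------------------------------------


def conv1d(x, weight, bias, stride: int) -> Tensor:
    """Strided 1-D convolution (cross-correlation), NCL layout.

    x: [B, C_in, L] (already padded), weight: [C_out, C_in, K], bias: [C_out].
    Output length is (L - K) // stride + 1.
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    B, C_in, L = x.shape
    C_out, C_in_w, K = weight.shape
    if C_in != C_in_w:
        raise ValueError("channel mismatch between input and kernel")
    L_out = (L - K) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)
    windows = windows[:, :, ::stride, :]            # [B, C_in, L_out, K]
    cols = windows.transpose(0, 2, 1, 3).reshape(B, L_out, C_in * K)
    w_flat = weight.data.reshape(C_out, C_in * K)
    out = cols @ w_flat.T + bias.data               # [B, L_out, C_out]
    out = out.transpose(0, 2, 1)                    # [B, C_out, L_out]

    def backward(g):
        g_blc = g.transpose(0, 2, 1)                # [B, L_out, C_out]
        g_bias = g_blc.sum(axis=(0, 1))
        g_wflat = np.einsum("blo,blk->ok", g_blc, cols)
        g_cols = g_blc @ w_flat                     # [B, L_out, C_in*K]
        g_cols = g_cols.reshape(B, L_out, C_in, K).transpose(0, 2, 1, 3)
        g_x = np.zeros((B, C_in, L))
        for k in range(K):
            idx = k + stride * np.arange(L_out)
            np.add.at(g_x, (slice(None), slice(None), idx), g_cols[..., k])
        return g_x, g_wflat.reshape(weight.shape), g_bias

    return _make(out, (x, weight, bias), backward)


# -- fused selective scan --------------------------------------------------


def _discretize(delta, A, Bm):
    """ZOH discretization broadcast over batch/length.

    delta: [B, L, E], A: [E, N] (strictly negative), Bm: [B, L, N].
    Returns dA, dB of shape [B, L, E, N].
    """
    dA = np.exp(delta[..., None] * A)               # [B, L, E, N]
    small = np.abs(A) < 1e-8
    A_safe = np.where(small, 1.0, A)
    coeff = np.where(small, delta[..., None], (dA - 1.0) / A_safe)
    dB = coeff * Bm[:, :, None, :]
    return dA, dB, A_safe, small


def selective_scan(u, delta, Bm, Cm, A) -> Tensor:
    """Input-dependent linear recurrence over the token axis.

    u, delta: [B, L, E]; Bm, Cm: [B, L, N]; A: [E, N] with negative entries.
    State s[l] (shape [B, E, N]) evolves as

        s[l] = exp(A * delta[l]) * s[l-1] + zoh(A, delta[l]) * B[l] * u[l]
        y[l, e] = sum_n s[l, e, n] * C[l, n]

    i.e. each output token reflects the state after absorbing its own input.
    Backward is explicit backpropagation through time.
    """
    u, delta = as_tensor(u), as_tensor(delta)
    Bm, Cm, A = as_tensor(Bm), as_tensor(Cm), as_tensor(A)
    B_, L, E = u.shape
    N = A.shape[1]
    dA, dB, A_safe, small = _discretize(delta.data, A.data, Bm.data)

    states = np.zeros((B_, L + 1, E, N))
    y = np.empty((B_, L, E))
    for l in range(L):
        states[:, l + 1] = (dA[:, l] * states[:, l]
                            + dB[:, l] * u.data[:, l, :, None])
        y[:, l] = np.einsum("ben,bn->be", states[:, l + 1], Cm.data[:, l])

    def backward(gy):
        gs = np.zeros((B_, E, N))
        gu = np.empty((B_, L, E))
        gC = np.empty((B_, L, N))
        g_dA = np.empty((B_, L, E, N))
        g_dB = np.empty((B_, L, E, N))
        for l in range(L - 1, -1, -1):
            gs = gs + gy[:, l, :, None] * Cm.data[:, l, None, :]
            gC[:, l] = np.einsum("be,ben->bn", gy[:, l], states[:, l + 1])
            g_dA[:, l] = gs * states[:, l]
            g_dB[:, l] = gs * u.data[:, l, :, None]
            gu[:, l] = (gs * dB[:, l]).sum(-1)
            gs = gs * dA[:, l]
        # through ZOH: dB = coeff * Bm with coeff = (e^{A d} - 1)/A, whose
        # delta-derivative is exactly e^{A d} = dA for every A
        coeff = np.where(small, delta.data[..., None], (dA - 1.0) / A_safe)
        gBm = (g_dB * coeff).sum(axis=2)
        BmE = Bm.data[:, :, None, :]
        d = delta.data[..., None]
        gdelta = (g_dA * A.data * dA + g_dB * BmE * dA).sum(axis=3)
        dcoeff_dA = np.where(small, 0.5 * d ** 2,
                             (d * dA * A_safe - (dA - 1.0)) / A_safe ** 2)
        gA = (g_dA * d * dA
              + g_dB * BmE * dcoeff_dA).sum(axis=(0, 1))
        return gu, gdelta, gBm, gC, gA

    return _make(y, (u, delta, Bm, Cm, A), backward)


# -- losses ----------------------------------------------------------------


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits against (soft) targets in [0,1]."""
    targets = np.asarray(targets, dtype=float)
    t = Tensor(targets)
    loss = add(mul(t, softplus(mul(logits, -1.0))),
               mul(Tensor(1.0 - targets), softplus(logits)))
    return tmean(loss)
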