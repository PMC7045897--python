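"""Minimal CPU layer library with explicit forward/backward passes.

Everything operates on single samples in ``(C, H, W)`` layout (the training
regime of interest is batch size 1).  Convolutions use im2col/col2im with
cached gather/scatter index tables, so both directions reduce to BLAS
matmuls plus one ``bincount`` scatter.  Transposed convolution is implemented
as the exact adjoint of a strided convolution, which guarantees the
gradient pair is consistent by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "GroupNorm",
    "LeakyReLU",
    "AvgPool2d",
    "sigmoid",
    "leaky_relu",
    "group_norm_forward",
]


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        # gradients accumulate in float64: group-norm backprop through
        # near-constant activations amplifies by 1/sqrt(var + eps) per layer,
        # which can exceed the float32 range even when forward is well-behaved
        self.grad = np.zeros(value.shape, dtype=np.float64)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0


def _he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


class _ColIndex:
    """Cached im2col gather indices for one (C, H, W, k, s, p) geometry."""

    def __init__(self, C: int, H: int, W: int, k: int, s: int, p: int):
        Hp, Wp = H + 2 * p, W + 2 * p
        Ho, Wo = _out_size(H, k, s, p), _out_size(W, k, s, p)
        ii = (s * np.arange(Ho))[:, None] + np.arange(k)[None, :]   # (Ho, k)
        jj = (s * np.arange(Wo))[:, None] + np.arange(k)[None, :]   # (Wo, k)
        # flat index into padded (C, Hp, Wp); column order (c, ki, kj)
        idx = (
            np.arange(C)[None, None, :, None, None] * (Hp * Wp)
            + ii[:, None, None, :, None] * Wp
            + jj[None, :, None, None, :]
        )  # (Ho, Wo, C, k, k)
        self.idx = np.ascontiguousarray(idx.reshape(Ho * Wo, C * k * k))
        self.shape_padded = (C, Hp, Wp)
        self.out_hw = (Ho, Wo)
        self.pad = p


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p)))


def _im2col(x: np.ndarray, table: _ColIndex) -> np.ndarray:
    xp = _pad(x, table.pad)
    return xp.reshape(-1)[table.idx]  # (Ho*Wo, C*k*k)


def _col2im(cols: np.ndarray, table: _ColIndex) -> np.ndarray:
    """Adjoint of _im2col: scatter-add columns back onto the (unpadded) grid."""
    C, Hp, Wp = table.shape_padded
    flat = np.bincount(
        table.idx.reshape(-1),
        weights=cols.reshape(-1).astype(np.float64),
        minlength=C * Hp * Wp,
    )
    xp = flat.reshape(C, Hp, Wp)
    p = table.pad
    if p:
        xp = xp[:, p:-p, p:-p]
    return xp.astype(cols.dtype)


class Conv2d:
    """k×k convolution, zero padding, arbitrary stride."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, pad=None, *,
                 rng: np.random.Generator, dtype=np.float32, bias=True):
        if pad is None:
            pad = kernel // 2
        self.in_ch, self.out_ch, self.k, self.s, self.p = in_ch, out_ch, kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.W = Param(_he_uniform(rng, (out_ch, fan_in), fan_in, dtype), "conv.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "conv.b") if bias else None
        self._table: _ColIndex | None = None
        self._cols: np.ndarray | None = None

    def _table_for(self, x: np.ndarray) -> _ColIndex:
        C, H, W = x.shape
        t = self._table
        if t is None or t.shape_padded != (C, H + 2 * self.p, W + 2 * self.p):
            t = _ColIndex(C, H, W, self.k, self.s, self.p)
            self._table = t
        return t

    def forward(self, x: np.ndarray) -> np.ndarray:
        t = self._table_for(x)
        cols = _im2col(x, t)
        self._cols = cols
        out = cols @ self.W.value.T
        if self.b is not None:
            out += self.b.value
        Ho, Wo = t.out_hw
        return out.T.reshape(self.out_ch, Ho, Wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        t = self._table
        dflat = dy.reshape(self.out_ch, -1).T  # (Ho*Wo, out_ch)
        self.W.grad += dflat.T @ self._cols
        if self.b is not None:
            self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.W.value
        self._cols = None
        return _col2im(dcols, t)

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def param_count(self) -> int:
        return self.W.value.size + (self.b.value.size if self.b is not None else 0)


class ConvTranspose2d:
    """k×k transposed convolution (learned upsampling).

    Forward is the adjoint of a stride-``s`` convolution mapping the *output*
    grid to the input grid; with kernel 3, stride 2, pad 1 the output is
    exactly twice the input size.
    """

    def __init__(self, in_ch, out_ch, kernel=3, stride=2, pad=1, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.in_ch, self.out_ch, self.k, self.s, self.p = in_ch, out_ch, kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        # weight laid out as the underlying conv's (in_ch=conv-out, out_ch*k*k)
        self.W = Param(_he_uniform(rng, (in_ch, out_ch * kernel * kernel), fan_in, dtype),
                       "deconv.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "deconv.b")
        self._table: _ColIndex | None = None
        self._x: np.ndarray | None = None

    def _table_for_out(self, Hout: int, Wout: int) -> _ColIndex:
        t = self._table
        if t is None or t.shape_padded != (self.out_ch, Hout + 2 * self.p, Wout + 2 * self.p):
            t = _ColIndex(self.out_ch, Hout, Wout, self.k, self.s, self.p)
            self._table = t
        return t

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        Hout, Wout = self.s * H, self.s * W
        t = self._table_for_out(Hout, Wout)
        if t.out_hw != (H, W):
            raise ValueError(f"transposed-conv geometry mismatch: {t.out_hw} vs {(H, W)}")
        self._x = x
        xflat = x.reshape(C, -1).T                    # (H*W, in_ch)
        cols = xflat @ self.W.value                   # (H*W, out_ch*k*k)
        out = _col2im(cols, t)                        # (out_ch, Hout, Wout)
        return out + self.b.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        t = self._table
        cols = _im2col(dy, t)                         # (H*W, out_ch*k*k)
        xflat = self._x.reshape(self.in_ch, -1).T
        self.W.grad += xflat.T @ cols
        self.b.grad += dy.sum(axis=(1, 2))
        dx = cols @ self.W.value.T                    # (H*W, in_ch)
        self._x = None
        H, W = t.out_hw
        return dx.T.reshape(self.in_ch, H, W)

    def params(self):
        return [self.W, self.b]

    def param_count(self) -> int:
        return self.W.value.size + self.b.value.size


class GroupNorm:
    """Group normalization over (C, H, W): per-group zero mean, unit variance,
    then learned per-channel scale/shift.  Stable at batch size 1."""

    def __init__(self, channels: int, groups: int, eps: float = 1e-5, dtype=np.float32):
        if channels % groups != 0:
            raise ValueError(f"channels ({channels}) not divisible by groups ({groups})")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.gamma = Param(np.ones(channels, dtype=dtype), "gn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "gn.beta")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        g = self.groups
        xg = x.reshape(g, -1)
        mu = xg.mean(axis=1, keepdims=True)
        var = xg.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(C, H, W)
        self._cache = (xhat, inv)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        C, H, W = dy.shape
        g = self.groups
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2))
        self.beta.grad += dy.sum(axis=(1, 2))
        dxhat = (dy * self.gamma.value[:, None, None]).reshape(g, -1)
        xh = xhat.reshape(g, -1)
        m = dxhat.shape[1]
        dx = inv * (dxhat - dxhat.mean(axis=1, keepdims=True)
                    - xh * (dxhat * xh).sum(axis=1, keepdims=True) / m)
        return dx.reshape(C, H, W).astype(dy.dtype)

    def params(self):
        return [self.gamma, self.beta]

    def param_count(self) -> int:
        return 2 * self.channels


class LeakyReLU:
    """y = x for x >= 0, alpha*x otherwise."""

    def __init__(self, alpha: float):
        if not 0 < alpha < 1:
            raise ValueError(f"leaky-ReLU slope must lie in (0, 1), got {alpha}")
        self.alpha = alpha
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m = self._mask
        self._mask = None
        return np.where(m, dy, self.alpha * dy)

    def params(self):
        return []

    def param_count(self) -> int:
        return 0


class AvgPool2d:
    """Non-overlapping k×k average pooling."""

    def __init__(self, k: int = 2):
        self.k = k
        self._in_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        k = self.k
        if H % k or W % k:
            raise ValueError(f"spatial size {(H, W)} not divisible by pool size {k}")
        self._in_shape = x.shape
        return x.reshape(C, H // k, k, W // k, k).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, H, W = self._in_shape
        k = self.k
        up = np.repeat(np.repeat(dy, k, axis=1), k, axis=2) / (k * k)
        return up.astype(dy.dtype)

    def params(self):
        return []

    def param_count(self) -> int:
        return 0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def leaky_relu(x, alpha: float):
    """Functional leaky ReLU: identity on non-negatives, slope ``alpha`` below."""
    if not 0 < alpha < 1:
        raise ValueError(f"leaky-ReLU slope must lie in (0, 1), got {alpha}")
    x = np.asarray(x)
    return np.where(x >= 0, x, alpha * x)


def group_norm_forward(x: np.ndarray, groups: int, eps: float = 1e-5) -> np.ndarray:
    """Functional group normalization (unit scale, zero shift)."""
    C = x.shape[0]
    if C % groups != 0:
        raise ValueError(f"channels ({C}) not divisible by groups ({groups})")
    xg = x.reshape(groups, -1)
    mu = xg.mean(axis=1, keepdims=True)
    var = xg.var(axis=1, keepdims=True)
    return ((xg - mu) / np.sqrt(var + eps)).reshape(x.shape)
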