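"""Minimal NumPy neural-network layers with hand-written backpropagation.

Every layer is a :class:`Module` exposing ``forward(x, training)`` and
``backward(grad_out) -> grad_in``; parameter gradients accumulate into
``Parameter.grad``.  Layers cache forward activations, so a module instance
must complete one forward/backward pair before being reused.  All math is
float64; correctness is pinned by finite-difference gradient checks in the
test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "GELU",
    "MaxPool1d",
    "LayerNorm",
    "Dropout",
    "MultiHeadAttention",
    "Sequential",
    "scaled_attention",
    "softmax",
    "truncated_normal",
]


def truncated_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal draws clipped at two standard deviations, then scaled."""
    return np.clip(rng.standard_normal(shape), -2.0, 2.0) * std


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def __repr__(self):  # pragma: no cover
        return f"Parameter({self.name}, shape={self.value.shape})"


class Module:
    """Base class; subclasses register parameters and submodules as attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}: "
                                 f"{arr.shape} vs {p.value.shape}")
            p.value[...] = arr


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 std: float | None = None, name: str = "linear"):
        if std is None:
            std = (1.0 / in_dim) ** 0.5
        self.W = Parameter(truncated_normal(rng, (in_dim, out_dim), std), f"{name}.W")
        self.b = Parameter(np.zeros(out_dim), f"{name}.b")
        self._x: np.ndarray | None = None

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad_out):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        g2 = grad_out.reshape(-1, grad_out.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return grad_out @ self.W.value.T


class Conv1d(Module):
    """1D convolution with 'same' zero padding, stride 1, odd kernel size.

    Input/output layout is (batch, channels, length).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator, name: str = "conv"):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.k = kernel_size
        std = (2.0 / (in_ch * kernel_size)) ** 0.5
        self.W = Parameter(
            truncated_normal(rng, (in_ch * kernel_size, out_ch), std), f"{name}.W")
        self.b = Parameter(np.zeros(out_ch), f"{name}.b")
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x, training=False):
        B, C, L = x.shape
        if C != self.in_ch:
            raise ValueError(f"conv expected {self.in_ch} channels, got {C}")
        pad = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (B, C, L, k) windows -> (B, L, C*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, L, C * self.k)
        self._cols = cols
        self._in_shape = (B, C, L)
        y = cols @ self.W.value + self.b.value  # (B, L, out_ch)
        return y.transpose(0, 2, 1)

    def backward(self, grad_out):
        B, C, L = self._in_shape
        pad = (self.k - 1) // 2
        g = grad_out.transpose(0, 2, 1)  # (B, L, out_ch)
        cols2 = self._cols.reshape(-1, C * self.k)
        g2 = g.reshape(-1, self.out_ch)
        self.W.grad += cols2.T @ g2
        self.b.grad += g2.sum(axis=0)
        gcols = (g @ self.W.value.T).reshape(B, L, C, self.k)
        gxp = np.zeros((B, C, L + 2 * pad))
        for j in range(self.k):
            gxp[:, :, j:j + L] += gcols[:, :, :, j].transpose(0, 2, 1)
        return gxp[:, :, pad:pad + L]


class BatchNorm1d(Module):
    """Per-channel normalization over (batch, length) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), f"{name}.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad_out):
        xhat, inv_std, training, shape = self._cache
        B, C, L = shape
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2))
        self.beta.grad += grad_out.sum(axis=(0, 2))
        gxhat = grad_out * self.gamma.value[None, :, None]
        if not training:
            return gxhat * inv_std[None, :, None]
        n = B * L
        m1 = gxhat.mean(axis=(0, 2))
        m2 = (gxhat * xhat).mean(axis=(0, 2))
        return inv_std[None, :, None] * (
            gxhat - m1[None, :, None] - xhat * m2[None, :, None])


class ReLU(Module):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class GELU(Module):
    """Exact Gaussian-error-linear unit, 0.5*x*(1 + erf(x/sqrt(2)))."""

    def forward(self, x, training=False):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        return x * self._cdf

    def backward(self, grad_out):
        x = self._x
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return grad_out * (self._cdf + x * pdf)


class MaxPool1d(Module):
    """Non-overlapping max pooling along the time axis; length must divide."""

    def __init__(self, pool_size: int):
        self.p = pool_size

    def forward(self, x, training=False):
        B, C, L = x.shape
        if L % self.p != 0:
            raise ValueError(f"max-pool: length {L} not divisible by pool {self.p}")
        xr = x.reshape(B, C, L // self.p, self.p)
        self._arg = np.argmax(xr, axis=3)
        self._in_shape = (B, C, L)
        return np.max(xr, axis=3)

    def backward(self, grad_out):
        B, C, L = self._in_shape
        g = np.zeros((B, C, L // self.p, self.p))
        np.put_along_axis(g, self._arg[..., None], grad_out[..., None], axis=3)
        return g.reshape(B, C, L)


class LayerNorm(Module):
    """Normalization over the last axis with learned scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5, name: str = "ln"):
        self.gamma = Parameter(np.ones(dim), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), f"{name}.beta")
        self.eps = eps

    def forward(self, x, training=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad_out):
        xhat = self._xhat
        axes = tuple(range(grad_out.ndim - 1))
        self.gamma.grad += (grad_out * xhat).sum(axis=axes)
        self.beta.grad += grad_out.sum(axis=axes)
        g = grad_out * self.gamma.value
        m1 = g.mean(axis=-1, keepdims=True)
        m2 = (g * xhat).mean(axis=-1, keepdims=True)
        return self._inv_std * (g - m1 - xhat * m2)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


def scaled_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                     d: float | None = None,
                     scale_mode: str = "sqrt") -> np.ndarray:
    """Scaled dot-product attention, softmax(Q K^T / scale) V.

    ``scale_mode='sqrt'`` divides scores by sqrt(d) (the standard convention);
    ``'linear'`` divides by d itself.  ``d`` defaults to the key width.
    Operates on the trailing two axes, so batched/stacked inputs work.
    """
    Q = np.asarray(Q, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"Q width {Q.shape[-1]} != K width {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError(f"K rows {K.shape[-2]} != V rows {V.shape[-2]}")
    if d is None:
        d = Q.shape[-1]
    scale = np.sqrt(d) if scale_mode == "sqrt" else float(d)
    scores = Q @ np.swapaxes(K, -1, -2) / scale
    return softmax(scores, axis=-1) @ V


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product self-attention on (batch, tokens, dim)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 scale_mode: str = "sqrt", name: str = "mha"):
        if dim % n_heads != 0:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.h = n_heads
        self.d = dim // n_heads
        self.scale_mode = scale_mode
        self.scale = np.sqrt(self.d) if scale_mode == "sqrt" else float(self.d)
        self.wq = Linear(dim, dim, rng, name=f"{name}.q")
        self.wk = Linear(dim, dim, rng, name=f"{name}.k")
        self.wv = Linear(dim, dim, rng, name=f"{name}.v")
        self.wo = Linear(dim, dim, rng, name=f"{name}.o")
        self.last_attention: np.ndarray | None = None

    def _split(self, x):  # (B,T,D) -> (B,h,T,d)
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.d).transpose(0, 2, 1, 3)

    def forward(self, x, training=False):
        B, T, _ = x.shape
        q = self._split(self.wq(x, training))
        k = self._split(self.wk(x, training))
        v = self._split(self.wv(x, training))
        scores = q @ np.swapaxes(k, -1, -2) / self.scale
        a = softmax(scores, axis=-1)              # (B,h,T,T)
        o = a @ v                                  # (B,h,T,d)
        self.last_attention = a
        self._cache = (q, k, v, a)
        concat = o.transpose(0, 2, 1, 3).reshape(B, T, self.dim)
        return self.wo(concat, training)

    def backward(self, grad_out):
        q, k, v, a = self._cache
        B, h, T, d = q.shape
        gconcat = self.wo.backward(grad_out)
        go = gconcat.reshape(B, T, h, d).transpose(0, 2, 1, 3)
        ga = go @ np.swapaxes(v, -1, -2)
        gv = np.swapaxes(a, -1, -2) @ go
        gs = a * (ga - np.sum(ga * a, axis=-1, keepdims=True))
        gq = gs @ k / self.scale
        gk = np.swapaxes(gs, -1, -2) @ q / self.scale

        def merge(t):  # (B,h,T,d) -> (B,T,D)
            return t.transpose(0, 2, 1, 3).reshape(B, T, self.dim)

        gx = self.wq.backward(merge(gq))
        gx = gx + self.wk.backward(merge(gk))
        gx = gx + self.wv.backward(merge(gv))
        return gx


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out
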