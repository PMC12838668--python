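"""Minimal numpy neural-network engine for the sequence classifier.

Implements exactly the pieces the staging model needs — 2-D convolution
(im2col), batch normalization, GELU, Dropout2D, average pooling, linear
layers, (bi)directional LSTM with backpropagation through time, a weighted
masked softmax cross-entropy, and Adam — with explicit forward/backward
methods and float32 arithmetic by default (float64 available for gradient
checking).  All randomness flows through a caller-supplied
``numpy.random.Generator`` so initialization and dropout are
seed-deterministic on a single CPU.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return cdf + x * pdf


class GELU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return _gelu(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * _gelu_grad(self._x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------


class Conv2d(Layer):
    """k x k convolution with 'same'-style padding, He-initialized."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        strided = view[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        cols = strided.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols)
        out = cols @ self.W.value.T + self.b.value
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, ho, wo = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        dout_r = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.W.grad += dout_r.T @ cols
        self.b.grad += dout_r.sum(axis=0)
        dcols = dout_r @ self.W.value  # (n*ho*wo, c*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[
                    :, :, :, :, ki, kj
                ]
        if p:
            return dxp[:, :, p : p + h, p : p + w]
        return dxp


# ---------------------------------------------------------------------------
# Normalization / regularization / pooling
# ---------------------------------------------------------------------------


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not train:
            return dxhat * inv_std[None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (
            inv_std[None, :, None, None]
            / m
            * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        )


class Dropout2d(Layer):
    """Channel dropout: whole feature maps are zeroed with probability p."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = (self.rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.p).astype(x.dtype)
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class AvgPool2d(Layer):
    """Non-overlapping f x f average pooling (input dims must divide by f)."""

    def __init__(self, f: int):
        self.f = f

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        f = self.f
        if h % f or w % f:
            raise ValueError(f"pooling factor {f} must divide spatial dims {(h, w)}")
        self._in_shape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        f = self.f
        return np.repeat(np.repeat(dout, f, axis=2), f, axis=3) / (f * f)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None], self._in_shape) / (h * w) + np.zeros(
            self._in_shape, dtype=dout.dtype
        )


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator, dtype=np.float32):
        bound = np.sqrt(6.0 / (din + dout))
        self.W = Param(rng.uniform(-bound, bound, size=(din, dout)).astype(dtype))
        self.b = Param(np.zeros(dout, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.W.value.T


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------


class LSTM(Layer):
    """Single-direction LSTM over (B, T, D) inputs; gates ordered i, f, g, o."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.din, self.hidden = din, hidden
        bx = np.sqrt(6.0 / (din + 4 * hidden))
        bh = np.sqrt(6.0 / (hidden + 4 * hidden))
        self.Wx = Param(rng.uniform(-bx, bx, size=(din, 4 * hidden)).astype(dtype))
        self.Wh = Param(rng.uniform(-bh, bh, size=(hidden, 4 * hidden)).astype(dtype))
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(b)

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        self._cache = []
        self._x = x
        out = np.empty((B, T, H), dtype=x.dtype)
        for t in range(T):
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            out[:, t] = h
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, D = x.shape
        H = self.hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = dout[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.Wx.grad += x[:, t].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and time-reversed passes, concatenated."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.fwd = LSTM(din, hidden, rng, dtype)
        self.bwd = LSTM(din, hidden, rng, dtype)
        self.hidden = hidden

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out_f = self.fwd.forward(x, train)
        out_b = self.bwd.forward(x[:, ::-1], train)[:, ::-1]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.hidden
        dx_f = self.fwd.backward(np.ascontiguousarray(dout[:, :, :H]))
        dx_b = self.bwd.backward(np.ascontiguousarray(dout[:, ::-1, H:]))[:, ::-1]
        return dx_f + dx_b


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def weighted_masked_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    class_weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy over valid (unmasked) slots.

    Returns (loss, dlogits).  Padded slots (mask False) contribute exactly
    zero to both; the loss is normalized by the summed weights of the valid
    slots so batches of different effective size are comparable.
    """
    B, T, K = logits.shape
    flat = logits.reshape(B * T, K).astype(np.float64)
    lab = labels.reshape(B * T)
    m = mask.reshape(B * T).astype(np.float64)
    w = class_weights[lab] * m
    shifted = flat - flat.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    p = expz / expz.sum(axis=1, keepdims=True)
    denom = w.sum()
    if denom <= 0:
        return 0.0, np.zeros_like(logits)
    logp = shifted - np.log(expz.sum(axis=1, keepdims=True))
    loss = -(w * logp[np.arange(B * T), lab]).sum() / denom
    dflat = p
    dflat[np.arange(B * T), lab] -= 1.0
    dflat *= (w / denom)[:, None]
    return float(loss), dflat.reshape(B, T, K).astype(logits.dtype)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with (coupled) L2 weight decay, matching the common default."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
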