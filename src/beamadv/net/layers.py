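"""Minimal vectorized neural-network layers with explicit backward passes.

Each layer exposes ``forward(x, train)`` and ``backward(dy)``; ``backward``
returns the gradient with respect to the layer input and accumulates parameter
gradients in ``grads`` (aligned with ``params``).  Everything is plain numpy so
runs are bit-reproducible given a seeded initialisation and single-threaded
BLAS; gradients — including the input gradient the white-box attacks need —
flow through the same code path as weight gradients.

Convolutions are computed as one GEMM per kernel offset (no im2col copy),
which keeps peak memory proportional to the activation size.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "MaxPool2d", "ReLU", "Dense", "Dropout",
    "Conv1dTemporal", "LSTM", "softmax", "cross_entropy_with_grad",
]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _row_windows(xp: np.ndarray, w_out: int, k: int) -> np.ndarray:
    """Overlapping horizontal k-windows of a channels-last padded tensor.

    Returns a zero-copy strided view (N, Hp, w_out, k*C) whose last axis walks
    k consecutive (width, channel) positions; valid because width x channel is
    contiguous in memory.
    """
    n, hp, wp, c = xp.shape
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, shape=(n, hp, w_out, k * c), strides=(s[0], s[1], s[2], s[3]), writeable=False
    )


class Conv2d(Layer):
    """kxk 2-D convolution, stride 1, 'same' zero padding, channels-last (N, H, W, C).

    The kernel is stored as k row-blocks of shape (k*Cin, Cout).  Forward and
    the input gradient are k matmuls against zero-copy horizontal-window views
    (the width x channel axis is contiguous, so BLAS sees well-shaped GEMMs);
    the weight gradient contracts the flattened padded input against the
    flattened padded output gradient at k*k relative offsets — the zero
    padding guarantees the terms that would cross row or sample boundaries
    vanish, so no patch matrix is ever materialized.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        self.W = _he_init(rng, (k, k * cin, cout), cin * k * k, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p, k = self.pad, self.k
        self._xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        N, H, W, _ = x.shape
        self._in_hw = (H, W)
        hv = _row_windows(self._xp, W, k)
        out = hv[:, 0:H] @ self.W[0]
        for i in range(1, k):
            out += hv[:, i : i + H] @ self.W[i]
        return out + self.b

    def _flipped_weights(self) -> np.ndarray:
        """(k, k*Cout, Cin) kernel of the transposed convolution."""
        k, C, Co = self.k, self.cin, self.cout
        Wk = self.W.reshape(k, k, C, Co)
        return Wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k, k * Co, C)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p, k, C, Co = self.pad, self.k, self.cin, self.cout
        H, W = self._in_hw
        N = dy.shape[0]
        self.grads[1] += dy.sum(axis=(0, 1, 2))
        dy0 = np.zeros((N, H + 2 * p, W + 2 * p, Co), dtype=dy.dtype)
        dy0[:, p : p + H, p : p + W, :] = dy
        # weight gradient: flat-offset contractions of padded input x padded dy
        X2 = self._xp.reshape(-1, C)
        Y2 = dy0.reshape(-1, Co)
        Wp = W + 2 * p
        gW = self.grads[0].reshape(k, k, C, Co)
        for i in range(k):
            for j in range(k):
                d = (i - p) * Wp + (j - p)
                if d >= 0:
                    g = X2[d:].T @ Y2[: len(Y2) - d]
                else:
                    g = X2[: len(X2) + d].T @ Y2[-d:]
                gW[i, j] += g.astype(gW.dtype)
        # input gradient: same-convolution of dy with the flipped, transposed kernel
        Wf = self._flipped_weights()
        hv = _row_windows(dy0, W, k)
        dx = hv[:, 0:H] @ Wf[0]
        for i in range(1, k):
            dx += hv[:, i : i + H] @ Wf[i]
        return dx


class MaxPool2d(Layer):
    """k x k max pooling with stride k, channels-last; trailing rows/cols cropped."""

    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        N, H, W, C = x.shape
        Ho, Wo = H // k, W // k
        self._in_shape = x.shape
        xr = x[:, : Ho * k, : Wo * k, :].reshape(N, Ho, k, Wo, k, C)
        windows = np.ascontiguousarray(xr.transpose(0, 1, 3, 2, 4, 5)).reshape(N, Ho, Wo, k * k, C)
        self._arg = windows.argmax(axis=3)
        return np.take_along_axis(windows, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        N, Ho, Wo, C = dy.shape
        dwin = np.zeros((N, Ho, Wo, k * k, C), dtype=dy.dtype)
        np.put_along_axis(dwin, self._arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : Ho * k, : Wo * k, :] = (
            dwin.reshape(N, Ho, Wo, k, k, C).transpose(0, 1, 3, 2, 4, 5).reshape(N, Ho * k, Wo * k, C)
        )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dense(Layer):
    def __init__(self, din: int, dout: int, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.W = _he_init(rng, (din, dout), din, dtype)
        self.b = np.zeros(dout, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Conv1dTemporal(Layer):
    """1-D convolution across the slice axis of (N, T, D) features, 'same' padding."""

    def __init__(self, din: int, dout: int, k: int = 3, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.k, self.pad = k, k // 2
        self.W = _he_init(rng, (k, din, dout), din * k, dtype)
        self.b = np.zeros(dout, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.pad
        self._xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        N, T, _ = x.shape
        out = np.broadcast_to(self.b, (N, T, self.b.size)).copy()
        for i in range(self.k):
            out += self._xp[:, i : i + T, :] @ self.W[i]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, T, _ = dy.shape
        dxp = np.zeros_like(self._xp)
        self.grads[1] += dy.sum(axis=(0, 1))
        for i in range(self.k):
            self.grads[0][i] += np.einsum("ntd,nto->do", self._xp[:, i : i + T, :], dy, optimize=True)
            dxp[:, i : i + T, :] += dy @ self.W[i].T
        p = self.pad
        return dxp[:, p : p + T, :]


class LSTM(Layer):
    """Single-layer LSTM over (N, T, D); returns the last hidden state (N, H)."""

    def __init__(self, din: int, hidden: int, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.hidden = hidden
        scale = 1.0 / np.sqrt(din + hidden)
        self.Wx = (rng.standard_normal((din, 4 * hidden)) * scale).astype(dtype)
        self.Wh = (rng.standard_normal((hidden, 4 * hidden)) * scale).astype(dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, T, _ = x.shape
        H = self.hidden
        h = np.zeros((N, H), dtype=x.dtype)
        c = np.zeros((N, H), dtype=x.dtype)
        self._x, self._cache = x, []
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i, f = self._sigmoid(z[:, :H]), self._sigmoid(z[:, H : 2 * H])
            g, o = np.tanh(z[:, 2 * H : 3 * H]), self._sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = o * tanh_c, c_new
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        N, T, D = x.shape
        H = self.hidden
        dx = np.zeros_like(x)
        dh, dc = dy.astype(x.dtype), np.zeros((N, H), dtype=x.dtype)
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            self.grads[0] += x[:, t, :].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)
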