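"""Victim-network assembly: shared per-slice conv stack, temporal head, classifier.

A sample is a sequence of T slices (topographic-map stacks or raw EEG images).
Every slice passes through the same convolutional stack; the T per-slice
feature vectors are then aggregated by one of four heads — element-wise max,
1-D temporal convolution, LSTM, or the concatenation of the latter two — and a
fully connected classifier emits 2-class logits.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    LSTM, Conv1dTemporal, Conv2d, Dense, Dropout, Layer, MaxPool2d, ReLU,
    cross_entropy_with_grad, softmax,
)

__all__ = ["VictimNet", "Adam", "HEADS"]

HEADS = ("maxpool", "temporal_conv", "lstm", "mixed_lstm")


class _TemporalMax(Layer):
    """Element-wise max over the slice axis: (N, T, D) -> (N, D)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        self._arg = x.argmax(axis=1)
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dy.dtype)
        np.put_along_axis(dx, self._arg[:, None, :], dy[:, None, :], axis=1)
        return dx


class _TemporalConvHead(Layer):
    """Temporal conv + ReLU, flattened: (N, T, D) -> (N, T * dout)."""

    def __init__(self, din: int, dout: int, k: int, rng: np.random.Generator, dtype):
        super().__init__()
        self.conv = Conv1dTemporal(din, dout, k, rng=rng, dtype=dtype)
        self.relu = ReLU()
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.relu.forward(self.conv.forward(x, train), train)
        self._nt = out.shape[:2]
        return out.reshape(out.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.reshape(self._nt + (-1,))
        return self.conv.backward(self.relu.backward(dy))


class _MixedHead(Layer):
    """Concatenated LSTM and temporal-conv paths over the same slice features."""

    def __init__(self, din: int, lstm_hidden: int, tconv_out: int, k: int,
                 rng: np.random.Generator, dtype):
        super().__init__()
        self.lstm = LSTM(din, lstm_hidden, rng=rng, dtype=dtype)
        self.tconv = _TemporalConvHead(din, tconv_out, k, rng, dtype)
        self.params = self.lstm.params + self.tconv.params
        self.grads = self.lstm.grads + self.tconv.grads
        self._split = lstm_hidden

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.concatenate([self.lstm.forward(x, train), self.tconv.forward(x, train)], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.lstm.backward(dy[:, : self._split]) + self.tconv.backward(dy[:, self._split:])


def _conv_stack(input_kind: str, rng: np.random.Generator, dtype) -> list[Layer]:
    cin = 4 if input_kind == "beam" else 1
    stack: list[Layer] = []
    for i in range(4):
        stack += [Conv2d(cin if i == 0 else 32, 32, rng=rng, dtype=dtype), ReLU()]
    stack.append(MaxPool2d(2))
    if input_kind == "eeg":
        for i in range(2):
            stack += [Conv2d(32 if i == 0 else 64, 64, rng=rng, dtype=dtype), ReLU()]
        stack.append(MaxPool2d(2))
        stack += [Conv2d(64, 128, rng=rng, dtype=dtype), ReLU(), MaxPool2d(2)]
    return stack


class VictimNet:
    """Full victim network with explicit forward/backward including input gradients.

    Parameters
    ----------
    input_kind : 'beam' (T x 4 x 22 x 22 slices) or 'eeg' (T x 1 x 22 x 256).
    head : one of :data:`HEADS`.
    slice_shape : (channels, height, width) of one slice.
    """

    def __init__(
        self,
        input_kind: str,
        head: str,
        slice_shape: tuple[int, int, int],
        n_slices: int = 5,
        fc_width: int = 512,
        lstm_hidden: int = 128,
        tconv_out: int = 64,
        tconv_kernel: int = 3,
        dropout: float = 0.0,
        n_classes: int = 2,
        seed: int = 0,
        dtype=np.float32,
    ):
        if input_kind not in ("beam", "eeg"):
            raise ValueError(f"unknown input kind {input_kind!r}")
        if head not in HEADS:
            raise ValueError(f"unknown head {head!r}; known: {HEADS}")
        self.input_kind, self.head_name = input_kind, head
        self.slice_shape, self.n_slices = tuple(slice_shape), n_slices
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.conv_stack = _conv_stack(input_kind, rng, dtype)
        # feature dimension after the stack, probed with a zero slice
        # (the stack runs channels-last internally)
        probe = np.zeros((1, slice_shape[1], slice_shape[2], slice_shape[0]), dtype=dtype)
        for layer in self.conv_stack:
            probe = layer.forward(probe)
        d = probe.size
        self.feature_dim = d
        if head == "maxpool":
            self.head = _TemporalMax()
            d_head = d
        elif head == "temporal_conv":
            self.head = _TemporalConvHead(d, tconv_out, tconv_kernel, rng, dtype)
            d_head = n_slices * tconv_out
        elif head == "lstm":
            self.head = LSTM(d, lstm_hidden, rng=rng, dtype=dtype)
            d_head = lstm_hidden
        else:
            self.head = _MixedHead(d, lstm_hidden, tconv_out, tconv_kernel, rng, dtype)
            d_head = lstm_hidden + n_slices * tconv_out
        self.classifier: list[Layer] = [Dense(d_head, fc_width, rng=rng, dtype=dtype), ReLU()]
        if dropout > 0:
            self.classifier.append(Dropout(dropout, rng))
        self.classifier.append(Dense(fc_width, n_classes, rng=rng, dtype=dtype))
        self._conv_out_shape = probe.shape[1:]

    # ---- plumbing ----------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        return [*self.conv_stack, self.head, *self.classifier]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()

    # ---- forward / backward -----------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        n, t = x.shape[:2]
        out = x.reshape(n * t, *self.slice_shape)
        out = np.ascontiguousarray(out.transpose(0, 2, 3, 1))  # to channels-last
        for layer in self.conv_stack:
            out = layer.forward(out, train)
        feats = out.reshape(n, t, -1)
        pooled = self.head.forward(feats, train)
        for layer in self.classifier:
            pooled = layer.forward(pooled, train)
        return pooled  # logits (n, n_classes)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dy = dlogits
        for layer in reversed(self.classifier):
            dy = layer.backward(dy)
        dfeats = self.head.backward(dy)
        n, t = dfeats.shape[:2]
        dy = dfeats.reshape(n * t, *self._conv_out_shape)
        for layer in reversed(self.conv_stack):
            dy = layer.backward(dy)
        dy = dy.transpose(0, 3, 1, 2)  # back to channels-first
        return dy.reshape(n, t, *self.slice_shape)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x).astype(np.float64))

    def loss_and_input_grad(self, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        """Cross-entropy at (x, y) and its gradient with respect to x."""
        logits = self.forward(x)
        loss, dlogits = cross_entropy_with_grad(logits, np.asarray(y))
        self.zero_grad()
        return loss, self.backward(dlogits).astype(np.float64)

    # ---- serialization ----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("parameter count mismatch")
        for i, p in enumerate(params):
            p[...] = state[f"p{i}"].astype(p.dtype)


class Adam:
    """Adam with optional decoupled L2 on matrix-shaped parameters."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, l2: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, betas[0], betas[1], eps, l2
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t, b2t = 1 - self.b1**self.t, 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            g64 = g.astype(np.float64)
            if self.l2 and p.ndim >= 2:
                g64 = g64 + self.l2 * p
            m[...] = self.b1 * m + (1 - self.b1) * g64
            v[...] = self.b2 * v + (1 - self.b2) * g64**2
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
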