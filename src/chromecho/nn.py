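"""Minimal numpy neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during forward, returns the
gradient with respect to its input from backward, and accumulates parameter
gradients in place.  Input gradients are always propagated — even through
frozen layers — because gradient-times-input attribution differentiates the
trained network with respect to its inputs.

Arrays are float32; 1-D convolutions operate on (batch, channels, width).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "Dense",
    "ReLU",
    "MaxPool1d",
    "CenterCrop1d",
    "GlobalMaxPool1d",
    "GlobalAvgPool1d",
    "Flatten",
    "Sequential",
    "SGD",
    "sigmoid",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []

    __call__ = lambda self, x: self.forward(x)


class Conv1d(Layer):
    """Stride-1 cross-correlation: y[b,o,t] = sum_{c,k} W[o,c,k] x[b,c,t+k] + b[o]."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: int = 0, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel
        self.W = Param(rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, kernel)), "conv.W")
        self.b = Param(np.zeros(c_out), "conv.b")
        self.padding = padding
        self.kernel = kernel
        self._win = None
        self._w_in = None

    def forward(self, x):
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        win = sliding_window_view(xp, self.kernel, axis=2)  # (B, C, Wout, k)
        self._win = win
        self._w_in = x.shape[2]
        return np.einsum("ock,bcwk->bow", self.W.value, win, optimize=True) + self.b.value[:, None]

    def backward(self, gy):
        gy = np.ascontiguousarray(gy, dtype=np.float32)
        self.W.grad += np.einsum("bow,bcwk->ock", gy, self._win, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2))
        k, p = self.kernel, self.padding
        gyp = np.pad(gy, ((0, 0), (0, 0), (k - 1, k - 1)))
        gwin = sliding_window_view(gyp, k, axis=2)  # (B, O, Win+2p, k)
        w_flip = self.W.value[:, :, ::-1]
        gxp = np.einsum("ock,bowk->bcw", w_flip, gwin, optimize=True)
        return gxp[:, :, p : p + self._w_in] if p else gxp

    def parameters(self):
        return [self.W, self.b]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        rng = rng or np.random.default_rng()
        self.W = Param(rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)), "dense.W")
        self.b = Param(np.zeros(n_out), "dense.b")
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        gy = np.asarray(gy, dtype=np.float32)
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T

    def parameters(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling along width; trailing remainder dropped."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x):
        s = self.size
        w = (x.shape[2] // s) * s
        xr = x[:, :, :w].reshape(x.shape[0], x.shape[1], w // s, s)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, gy):
        B, C, W = self._shape
        s = self.size
        n = W // s
        gx = np.zeros((B, C, n, s), dtype=np.float32)
        np.put_along_axis(gx, self._arg[..., None], gy[..., None].astype(np.float32), axis=3)
        out = np.zeros((B, C, W), dtype=np.float32)
        out[:, :, : n * s] = gx.reshape(B, C, n * s)
        return out


class CenterCrop1d(Layer):
    """Keep the central fraction of the width axis.

    Used before a global max readout so the motif-presence signal is read
    from the labeled central bin rather than from the flanking context.
    """

    def __init__(self, keep_frac: float):
        if not 0.0 < keep_frac <= 1.0:
            raise ValueError("keep_frac must be in (0, 1]")
        self.keep_frac = keep_frac

    def forward(self, x):
        w = x.shape[2]
        keep = max(1, int(round(w * self.keep_frac)))
        self._lo = (w - keep) // 2
        self._w = w
        return x[:, :, self._lo : self._lo + keep]

    def backward(self, gy):
        gx = np.zeros(gy.shape[:2] + (self._w,), dtype=np.float32)
        gx[:, :, self._lo : self._lo + gy.shape[2]] = gy
        return gx


class GlobalMaxPool1d(Layer):
    """Max over the width axis: (B, C, W) -> (B, C).

    The canonical readout for motif presence: an activation anywhere in the
    window counts, independent of position.
    """

    def forward(self, x):
        self._arg = x.argmax(axis=2)
        self._shape = x.shape
        return x.max(axis=2)

    def backward(self, gy):
        gx = np.zeros(self._shape, dtype=np.float32)
        np.put_along_axis(gx, self._arg[..., None], gy[..., None].astype(np.float32), axis=2)
        return gx


class GlobalAvgPool1d(Layer):
    """Mean over the width axis: (B, C, W) -> (B, C)."""

    def forward(self, x):
        self._w = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy):
        return np.repeat(gy[:, :, None], self._w, axis=2).astype(np.float32) / self._w


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


def zero_grads(params: list[Param]) -> None:
    for p in params:
        p.grad[...] = 0.0


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s


def checksum(params: list[Param]) -> float:
    """Order-dependent parameter checksum, for frozen-layer audits."""
    return float(sum(float(np.abs(p.value).sum()) for p in params))


class SGD:
    """Stochastic gradient descent with classical momentum.

    v <- momentum * v + grad;  param <- param - lr * v.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v

    def zero_grad(self) -> None:
        zero_grads(self.params)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
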