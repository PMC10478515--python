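"""Minimal feed-forward neural-network layers with hand-written backprop.

The networks used here are small (two convolutions, two fully connected
layers), so the layers are implemented directly on numpy arrays: convolutions
via im2col + BLAS matmul, explicit backward passes, and an Adam optimizer.
All arrays are float32; every layer caches what its backward pass needs
during ``forward`` and releases it on ``backward``.

Layout conventions: images are ``(N, C, H, W)``; dense activations are
``(N, features)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "Linear",
    "ReLU",
    "BatchNorm",
    "MaxPool2x2",
    "Flatten",
    "L2Normalize",
    "Sequential",
    "Adam",
    "init_gaussian",
]


class Layer:
    """Base class: parameters are (name -> array) dicts, grads mirror them."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def weight_arrays(self) -> list[np.ndarray]:
        """Multiplicative weights only (excludes biases and norm shifts)."""
        return [v for k, v in self.params.items() if k == "W" or k == "gamma"]

    def state(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32).copy()


class Conv2d(Layer):
    """Valid (no padding) stride-1 convolution with a square kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 5):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.params = {
            "W": np.zeros((out_channels, in_channels, kernel, kernel), np.float32),
            "b": np.zeros(out_channels, np.float32),
        }
        self._cache = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (N, C, H, W) -> (N, L, C*k*k) with L = out_h*out_w
        k = self.kernel
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,oh,ow,k,k
        n, c, oh, ow = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
        return np.ascontiguousarray(cols)

    def forward(self, x, train=False):
        k = self.kernel
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if h < k or w < k:
            raise ValueError(f"input {h}x{w} smaller than {k}x{k} kernel")
        oh, ow = h - k + 1, w - k + 1
        cols = self._im2col(x)
        wmat = self.params["W"].reshape(self.out_channels, -1)
        out = cols @ wmat.T + self.params["b"]
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape = self._cache
        self._cache = None
        n, _, oh, ow = dout.shape
        k = self.kernel
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_channels)
        cols2 = cols.reshape(n * oh * ow, -1)
        self.grads["W"] = (dflat.T @ cols2).reshape(self.params["W"].shape)
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].reshape(self.out_channels, -1)).reshape(
            n, oh, ow, self.in_channels, k, k
        )
        dx = np.zeros(x_shape, np.float32)
        # scatter-add each kernel offset; k*k iterations keep this cheap
        for di in range(k):
            for dj in range(k):
                dx[:, :, di : di + oh, dj : dj + ow] += dcols[
                    :, :, :, :, di, dj
                ].transpose(0, 3, 1, 2)
        return dx


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.params = {
            "W": np.zeros((out_features, in_features), np.float32),
            "b": np.zeros(out_features, np.float32),
        }
        self._cache = None

    def forward(self, x, train=False):
        if train:
            self._cache = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        x = self._cache
        self._cache = None
        self.grads["W"] = dout.T @ x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial dims for 4-D input).

    Uses batch statistics in training mode and exponential running
    statistics in inference mode.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, np.float32),
            "beta": np.zeros(channels, np.float32),
        }
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._cache = None

    @staticmethod
    def _axes(x: np.ndarray) -> tuple[int, ...]:
        return (0, 2, 3) if x.ndim == 4 else (0,)

    def _shape(self, x: np.ndarray) -> tuple[int, ...]:
        return (1, self.channels, 1, 1) if x.ndim == 4 else (1, self.channels)

    def forward(self, x, train=False):
        axes, shp = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv_std.reshape(shp)
        if train:
            self._cache = (xhat, inv_std)
        return self.params["gamma"].reshape(shp) * xhat + self.params["beta"].reshape(shp)

    def backward(self, dout):
        xhat, inv_std = self._cache
        self._cache = None
        axes, shp = self._axes(dout), self._shape(dout)
        m = float(np.prod([dout.shape[a] for a in axes]))
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"].reshape(shp)
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shp)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp)
        ) * inv_std.reshape(shp)
        return dx.astype(np.float32)

    def state(self):
        s = dict(self.params)
        s["running_mean"] = self.running_mean
        s["running_var"] = self.running_var
        return s

    def load_state(self, state):
        super().load_state(state)
        self.running_mean = np.asarray(state["running_mean"], np.float32).copy()
        self.running_var = np.asarray(state["running_var"], np.float32).copy()


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2 (even input dims required)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2x2 needs even spatial dims, got {h}x{w}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = blocks.max(axis=(3, 5))
        if train:
            self._mask = blocks == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, dout):
        mask, shape = self._mask, self._shape
        self._mask = None
        # ties split the gradient equally between tied positions
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = mask * (dout[:, :, :, None, :, None] / counts)
        return d.reshape(shape).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class L2Normalize(Layer):
    """Project each row onto the unit sphere: z = u / |u|_2."""

    def __init__(self, eps: float = 1e-12):
        super().__init__()
        self.eps = eps

    def forward(self, x, train=False):
        norm = np.sqrt((x * x).sum(axis=1, keepdims=True)) + self.eps
        z = x / norm
        if train:
            self._cache = (z, norm)
        return z

    def backward(self, dout):
        z, norm = self._cache
        self._cache = None
        return (dout - (dout * z).sum(axis=1, keepdims=True) * z) / norm


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, k) for layer in self.layers for k in layer.params]

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                out[f"layer{i}.{k}"] = v.copy()
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            sub = {
                k.split(".", 1)[1]: v
                for k, v in state.items()
                if k.startswith(f"layer{i}.")
            }
            if sub:
                layer.load_state(sub)


def init_gaussian(net: Sequential, rng: np.random.Generator, std: float = 0.2,
                  mean: float = 0.0) -> None:
    """Draw every multiplicative weight i.i.d. N(mean, std^2); biases and
    batch-norm shifts stay at their zero/one defaults."""
    for layer in net.layers:
        if "W" in layer.params:
            layer.params["W"] = rng.normal(
                mean, std, size=layer.params["W"].shape
            ).astype(np.float32)


class Adam:
    """Adam optimizer over a Sequential's parameters."""

    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in net.layers if l.params}
        self.v = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in net.layers if l.params}

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for layer in self.net.layers:
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m = self.m[id(layer)][k]
                v = self.v[id(layer)][k]
                m += (1 - self.beta1) * (g - m)
                v += (1 - self.beta2) * (g * g - v)
                layer.params[k] = (
                    p - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                ).astype(np.float32)
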