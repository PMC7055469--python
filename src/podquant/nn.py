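"""Minimal CPU neural-network engine used by the patch classifiers.

Layers operate on float32 channels-last (N, H, W, C) tensors and implement
explicit forward / backward passes.  Stride-1 convolutions avoid im2col
lowering altogether: with channels last, shifting the flattened padded
tensor by one receptive-field offset yields a contiguous (positions x
channels) matrix, so a k x k convolution is k*k BLAS matrix products
accumulated in place.  Entries contaminated by wrap-around at row or batch
boundaries land only in padding positions that are sliced away.

The engine covers exactly what the two classifiers need: convolution,
max/average pooling, batch normalization, ReLU, dropout, dense layers,
global average pooling, softmax cross-entropy and SGD with momentum and
weight decay.  All randomness (weight init, dropout masks) flows through
the ``numpy.random.Generator`` passed in by the caller; there is no global
random state.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "MaxPool2",
    "AvgPool2",
    "GlobalAvgPool",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


def _as_f32(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32)


class Layer:
    """Base layer: parameters live in ``params``, gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 2D convolution on (N, H, W, C) tensors.

    ``pad=0`` gives a valid convolution (output H-k+1), ``pad=k//2`` the
    usual same-size convolution.  Weights have shape (k, k, cin, cout).
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 pad: int = 0):
        super().__init__()
        self.cin, self.cout, self.k, self.pad = cin, cout, k, pad
        fan_in = cin * k * k
        # He initialization for ReLU networks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, cin, cout))
        self.params = {"w": _as_f32(w), "b": np.zeros(cout, dtype=np.float32)}

    def forward(self, x, train):
        n, h, w, c = x.shape
        k, pad = self.k, self.pad
        if pad:
            x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        hp, wp = x.shape[1], x.shape[2]
        oh, ow = hp - k + 1, wp - k + 1
        xseq = np.ascontiguousarray(x, dtype=np.float32).reshape(-1, c)
        self._xseq, self._hp, self._wp, self._n = xseq, hp, wp, n
        self._in_shape = (n, h, w, c)
        total = n * hp * wp
        L = total - (k - 1) * wp - (k - 1)
        yseq = np.zeros((total, self.cout), dtype=np.float32)
        wmat = self.params["w"]
        if k == 1:
            np.matmul(xseq, wmat[0, 0], out=yseq)
        else:
            for di in range(k):
                for dj in range(k):
                    o = di * wp + dj
                    yseq[:L] += xseq[o:o + L] @ wmat[di, dj]
        yseq += self.params["b"]
        # valid outputs: receptive-field top-left positions inside the grid
        return yseq.reshape(n, hp, wp, self.cout)[:, :oh, :ow]

    def backward(self, dout):
        n, hp, wp = self._n, self._hp, self._wp
        k = self.k
        oh, ow = hp - k + 1, wp - k + 1
        total = n * hp * wp
        L = total - (k - 1) * wp - (k - 1)
        xseq = self._xseq
        wmat = self.params["w"]

        # scatter dout onto the padded grid (zeros at discarded positions)
        dyp = np.zeros((n, hp, wp, self.cout), dtype=np.float32)
        dyp[:, :oh, :ow] = dout
        dyseq = dyp.reshape(-1, self.cout)

        dw = np.empty_like(wmat)
        dxseq = np.zeros((total, self.cin), dtype=np.float32)
        if k == 1:
            np.matmul(xseq.T, dyseq, out=dw[0, 0])
            np.matmul(dyseq, wmat[0, 0].T, out=dxseq)
        else:
            for di in range(k):
                for dj in range(k):
                    o = di * wp + dj
                    dw[di, dj] = xseq[o:o + L].T @ dyseq[:L]
                    dxseq[o:o + L] += dyseq[:L] @ wmat[di, dj].T
        self.grads["w"] = dw
        self.grads["b"] = dyseq.sum(axis=0)
        dxp = dxseq.reshape(n, hp, wp, self.cin)
        pad = self.pad
        if pad:
            return dxp[:, pad:hp - pad, pad:wp - pad]
        return dxp


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (even spatial sizes only)."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        # break ties so each window routes gradient to one element
        cum = np.cumsum(mask, axis=2)
        cum = np.cumsum(cum, axis=4)
        self._mask = mask & (cum == 1)
        self._xshape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._xshape
        dxr = self._mask * dout[:, :, None, :, None, :]
        return dxr.reshape(n, h, w, c)


class AvgPool2(Layer):
    def forward(self, x, train):
        n, h, w, c = x.shape
        self._xshape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dout):
        n, h, w, c = self._xshape
        dx = np.broadcast_to(
            dout[:, :, None, :, None, :] * np.float32(0.25),
            (n, h // 2, 2, w // 2, 2, c))
        return dx.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._xshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._xshape
        scale = np.float32(1.0 / (h * w))
        return np.broadcast_to(dout[:, None, None, :] * scale,
                               self._xshape).copy()


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params = {
            "gamma": np.ones(c, dtype=np.float32),
            "beta": np.zeros(c, dtype=np.float32),
        }
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean
                                 + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var
                                + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._xhat, self._inv = xhat, inv
        self._train_mode = train
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.params["gamma"]
        if not self._train_mode:
            # running statistics are constants w.r.t. the input
            return dxhat * inv
        dx = (dxhat
              - dxhat.mean(axis=(0, 1, 2), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 1, 2), keepdims=True))
        return dx * inv


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.p)
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout))
        self.params = {"w": _as_f32(w), "b": np.zeros(nout, dtype=np.float32)}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameter_layers(self):
        return [l for l in self.layers if l.params]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay."""

    def __init__(self, layers: list[Layer], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [{k: np.zeros_like(v) for k, v in l.params.items()}
                     for l in self.layers]

    def step(self):
        for layer, vel in zip(self.layers, self._vel):
            for name, p in layer.params.items():
                g = layer.grads[name] + self.weight_decay * p
                v = vel[name]
                v *= self.momentum
                v -= self.lr * g
                p += v
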