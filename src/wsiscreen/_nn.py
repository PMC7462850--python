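"""Minimal CPU neural-network framework (NHWC, manual backprop).

Implements exactly the pieces the segmentation and style-normalization
models need: stride-1 same-padding convolutions, 2x2 max/avg pooling,
nearest-neighbour upsampling, spatial dropout, instance normalization,
pointwise activations, softmax cross-entropy / L1 / least-squares losses,
and SGD-with-momentum / Adam optimizers.  All state is plain numpy arrays,
so models are picklable and bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base class: forward caches what backward needs; params() lists Params."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (N, H+2p, W+2p, C) -> (N*H*W, k*k*C)
    v = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, H, W, C, k, k)
    v = v.transpose(0, 1, 2, 4, 5, 3)  # (N, H, W, k, k, C)
    n, h, w = v.shape[:3]
    return v.reshape(n * h * w, k * k * x.shape[3]), (n, h, w)


class Conv2d(Layer):
    """Stride-1, same-padding 2-D convolution, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None, bias: bool = True):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * cin
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k * k * cin, cout))
        self.k, self.cin, self.cout = k, cin, cout
        self.w = Param(w)
        self.b = Param(np.zeros(cout)) if bias else None
        self._cols = None
        self._shape = None

    def forward(self, x, train=False):
        xp = _pad_same(x, self.k)
        cols, (n, h, w) = _im2col(xp, self.k)
        y = cols @ self.w.value
        if self.b is not None:
            y += self.b.value
        self._shape = (n, h, w)
        self._cols = cols if train else None
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy):
        n, h, w = self._shape
        dyf = dy.reshape(n * h * w, self.cout)
        self.w.grad += (self._cols.T @ dyf).astype(np.float32)
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0).astype(np.float32)
        # dx = conv(dy, W flipped, channels swapped); exact for stride-1 same conv
        wb = self.w.value.reshape(self.k, self.k, self.cin, self.cout)
        wb = wb[::-1, ::-1].transpose(0, 1, 3, 2).reshape(self.k * self.k * self.cout, self.cin)
        dyp = _pad_same(dy, self.k)
        cols, _ = _im2col(dyp, self.k)
        dx = (cols @ wb).reshape(n, h, w, self.cin)
        self._cols = None
        return dx

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class ReLU(Layer):
    def forward(self, x, train=False):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._m = x > 0
        return np.where(self._m, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._m, dy, self.alpha * dy)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class MaxPool2(Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        v = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = v.max(axis=(2, 4))
        self._mask = v == y[:, :, None, :, None, :]
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, h, w, c = self._shape
        d = self._mask * dy[:, :, None, :, None, :]
        return d.reshape(n, h, w, c)


class AvgPool2(Layer):
    def forward(self, x, train=False):
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dy):
        n, h, w, c = self._shape
        d = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * 0.25
        return d


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class SpatialDropout(Layer):
    """Drops whole feature channels per sample; identity at inference."""

    def __init__(self, p: float, rng=None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout fraction must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._m = None
            return x
        n, _, _, c = x.shape
        keep = (self.rng.random((n, 1, 1, c)) >= self.p) / (1.0 - self.p)
        self._m = keep.astype(np.float32)
        return x * self._m

    def backward(self, dy):
        return dy if self._m is None else dy * self._m


class InstanceNorm(Layer):
    """Per-sample per-channel normalization over the spatial axes, affine."""

    EPS = 1e-5

    def __init__(self, c: int):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def forward(self, x, train=False):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.EPS)
        self._xh = (x - mu) * self._inv
        return self._xh * self.gamma.value + self.beta.value

    def backward(self, dy):
        n, h, w, c = dy.shape
        m = h * w
        self.gamma.grad += (dy * self._xh).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxh = dy * self.gamma.value
        t1 = dxh.sum(axis=(1, 2), keepdims=True)
        t2 = (dxh * self._xh).sum(axis=(1, 2), keepdims=True)
        return self._inv * (dxh - t1 / m - self._xh * t2 / m)

    def params(self):
        return [self.gamma, self.beta]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout)))
        self.b = Param(np.zeros(cout))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T

    def params(self):
        return [self.w, self.b]


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).copy()


# ---------------------------------------------------------------- losses

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray):
    """Mean categorical cross-entropy over all leading axes.

    ``target`` is one-hot along the last axis. Returns (loss, dlogits).
    """
    p = softmax(logits)
    n = int(np.prod(logits.shape[:-1]))
    loss = -float((target * np.log(p + 1e-12)).sum()) / n
    return loss, (p - target) / n


def l1_loss(pred: np.ndarray, target: np.ndarray):
    n = pred.size
    d = pred - target
    return float(np.abs(d).mean()), np.sign(d) / n


def lsgan_loss(pred: np.ndarray, target_value: float):
    """Least-squares adversarial loss: mean (pred - t)^2."""
    d = pred - target_value
    return float((d**2).mean()), 2.0 * d / d.size


# ------------------------------------------------------------- optimizers

class SGD:
    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


class Adam:
    def __init__(self, params, lr, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params, self.lr = params, lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self._t += 1
        b1t = 1.0 - self.b1**self._t
        b2t = 1.0 - self.b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_weights(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_weights(params: list[Param], weights: list[np.ndarray]) -> None:
    if len(params) != len(weights):
        raise ValueError("weight list length mismatch")
    for p, w in zip(params, weights):
        p.value[...] = w
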