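"""Minimal CNN building blocks in numpy with hand-written backpropagation.

The desk-scale convolutional VAEs in this package run on small images
(32-128 px), where explicit im2col convolutions in numpy are fast enough for
training. Every layer implements ``forward(x, training)`` and
``backward(grad_out)``; parameters and their gradients live in per-layer
dicts so models can assert disjoint parameter registries. Tensors use NCHW
layout, float32.

All layers are gradient-checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "Sigmoid",
    "Dropout",
    "Linear",
    "Flatten",
    "Reshape",
    "Upsample2x",
    "Sequential",
    "Adam",
]


class Layer:
    """Base layer: stateless unless it declares params/grads dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    sn, sc, sh, sw = x.strides
    cols = as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    return np.ascontiguousarray(cols).reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(gcols: np.ndarray, xshape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back onto the image."""
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    g = gcols.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, pad: int = 1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization for leaky-ReLU nets
        self.params["W"] = (rng.standard_normal((cout, fan_in)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def forward(self, x, training=False):
        self._xshape = x.shape
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        y = np.einsum("of,nfp->nop", self.params["W"], cols, optimize=True)
        y += self.params["b"][None, :, None]
        return y.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, gout):
        n, cout, ho, wo = gout.shape
        g = gout.reshape(n, cout, ho * wo)
        self.grads["W"] = np.einsum("nop,nfp->of", g, self._cols, optimize=True)
        self.grads["b"] = g.sum(axis=(0, 2))
        gcols = np.einsum("of,nop->nfp", self.params["W"], g, optimize=True)
        return _col2im(gcols, self._xshape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        self._training = training
        return self.params["gamma"][None, :, None, None] * self._xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, gout):
        xhat = self._xhat
        self.grads["gamma"] = (gout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.params["gamma"][None, :, None, None]
        if not self._training:
            return gxhat / self._std
        # standard batch-norm backward through the batch statistics
        return (
            gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout):
        return np.where(self._mask, gout, self.slope * gout)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gout):
        return gout * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; the mask RNG is owned by the model for determinism."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError(f"dropout probability must lie in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / nin)
        self.params["W"] = (rng.standard_normal((nin, nout)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(nout, dtype=np.float32)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        self.grads["W"] = self._x.T @ gout
        self.grads["b"] = gout.sum(axis=0)
        return gout @ self.params["W"].T


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Reshape(Layer):
    """Reshape (N, nin) to (N, *tail)."""

    def __init__(self, tail: tuple[int, ...]):
        super().__init__()
        self.tail = tail

    def forward(self, x, training=False):
        return x.reshape(x.shape[0], *self.tail)

    def backward(self, gout):
        return gout.reshape(gout.shape[0], -1)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x, training=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gout):
        n, c, h, w = gout.shape
        return gout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def named_params(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"{prefix}{i}.{type(layer).__name__}.{name}", layer, name


class Adam:
    """Adam optimizer over (layer, param-name) slots."""

    def __init__(self, slots, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slots = list(slots)  # (layer, name)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[name].dtype
            )
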