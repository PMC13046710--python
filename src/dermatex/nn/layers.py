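"""Minimal NumPy layer library with reverse-mode gradients.

Conventions: channels-last tensors (``(N, H, W, C)`` for 2-D,
``(N, L, C)`` for 1-D), float32 computation.  Each layer caches what
its most recent ``forward`` needs for ``backward``; parameters are
``Param`` objects accumulating gradients in place, consumed by the
``Adam`` optimizer.  Convolutions use "same" padding at stride 1 (the
only configuration the architecture needs); max-pooling has stride =
window and floors odd extents.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Layer", "Conv2D", "Conv1D", "ReLU", "BatchNorm",
           "MaxPool2D", "MaxPool1D", "Flatten", "Dense", "Sequential",
           "Adam", "softmax", "softmax_cross_entropy"]


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    name = "layer"

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2D(Layer):
    """3x3 (or k x k) convolution, stride 1, same padding, channels-last."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, *,
                 rng: np.random.Generator, name: str = "conv2d"):
        assert k % 2 == 1
        self.k, self.c_in, self.c_out, self.name = k, c_in, c_out, name
        self.W = Param(_he_init(rng, (k, k, c_in, c_out), k * k * c_in),
                       name + ".W")
        self.b = Param(np.zeros(c_out), name + ".b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._x_shape = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        n, h, w, _ = x.shape
        out = np.broadcast_to(self.b.value, (n, h, w, self.c_out)).copy()
        for di in range(self.k):
            for dj in range(self.k):
                out += xp[:, di:di + h, dj:dj + w, :] @ self.W.value[di, dj]
        return out

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        n, h, w, _ = self._x_shape
        p = self.k // 2
        dxp = np.zeros_like(self._xp)
        for di in range(self.k):
            for dj in range(self.k):
                patch = self._xp[:, di:di + h, dj:dj + w, :]
                self.W.grad[di, dj] += np.tensordot(
                    patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di:di + h, dj:dj + w, :] += grad @ self.W.value[di, dj].T
        self.b.grad += grad.sum(axis=(0, 1, 2))
        return dxp[:, p:-p or None, p:-p or None, :]


class Conv1D(Layer):
    """Length-k convolution, stride 1, same padding, channels-last."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, *,
                 rng: np.random.Generator, name: str = "conv1d"):
        assert k % 2 == 1
        self.k, self.c_in, self.c_out, self.name = k, c_in, c_out, name
        self.W = Param(_he_init(rng, (k, c_in, c_out), k * c_in), name + ".W")
        self.b = Param(np.zeros(c_out), name + ".b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._x_shape = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp = xp
        n, length, _ = x.shape
        out = np.broadcast_to(self.b.value, (n, length, self.c_out)).copy()
        for d in range(self.k):
            out += xp[:, d:d + length, :] @ self.W.value[d]
        return out

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        n, length, _ = self._x_shape
        p = self.k // 2
        dxp = np.zeros_like(self._xp)
        for d in range(self.k):
            patch = self._xp[:, d:d + length, :]
            self.W.grad[d] += np.tensordot(patch, grad,
                                           axes=([0, 1], [0, 1]))
            dxp[:, d:d + length, :] += grad @ self.W.value[d].T
        self.b.grad += grad.sum(axis=(0, 1))
        return dxp[:, p:-p or None, :]


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class BatchNorm(Layer):
    """Per-channel batch normalization over all non-channel axes."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5, name: str = "batchnorm"):
        self.name = name
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels), name + ".gamma")
        self.beta = Param(np.zeros(channels), name + ".beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std.astype(np.float32), train, axes,
                       int(np.prod([x.shape[a] for a in axes])))
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv_std, train, axes, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        if not train:
            return g * inv_std
        gs = g.sum(axis=axes)
        gx = (g * xhat).sum(axis=axes)
        return inv_std / n * (n * g - gs - xhat * gx)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd extents are floored (cropped)."""

    def __init__(self, name: str = "maxpool2d"):
        self.name = name

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2, :]
        self._x_shape = x.shape
        x4 = xc.reshape(n, h2, 2, w2, 2, c)
        out = x4.max(axis=(2, 4))
        mask = x4 == out[:, :, None, :, None, :]
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, grad):
        n, h, w, c = self._x_shape
        h2, w2 = h // 2, w // 2
        g4 = self._mask * grad[:, :, None, :, None, :]
        dx = np.zeros(self._x_shape, dtype=np.float32)
        dx[:, : h2 * 2, : w2 * 2, :] = g4.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class MaxPool1D(Layer):
    """Size-2, stride-2 max pooling over the length axis; floors odd lengths."""

    def __init__(self, name: str = "maxpool1d"):
        self.name = name

    def forward(self, x, train=False):
        n, length, c = x.shape
        l2 = length // 2
        self._x_shape = x.shape
        x3 = x[:, : l2 * 2, :].reshape(n, l2, 2, c)
        out = x3.max(axis=2)
        mask = x3 == out[:, :, None, :]
        self._mask = mask / mask.sum(axis=2, keepdims=True)
        return out

    def backward(self, grad):
        n, length, c = self._x_shape
        l2 = length // 2
        g3 = self._mask * grad[:, :, None, :]
        dx = np.zeros(self._x_shape, dtype=np.float32)
        dx[:, : l2 * 2, :] = g3.reshape(n, l2 * 2, c)
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, *, bias: bool = True,
                 rng: np.random.Generator, name: str = "dense"):
        self.name = name
        self.W = Param(_he_init(rng, (n_in, n_out), n_in), name + ".W")
        self.b = Param(np.zeros(n_out), name + ".b") if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        self._x = np.ascontiguousarray(x, dtype=np.float32)
        out = self._x @ self.W.value
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        self.W.grad += self._x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer], name: str = "sequential"):
        self.layers = layers
        self.name = name

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with a mutable learning rate (for step-decay schedules)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(np.maximum(probs[np.arange(n), labels], 1e-12)).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)
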