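"""Minimal convolutional-network layers with explicit forward/backward.

The weakly supervised patch classifier and the bright-field-to-fluorescence
translator need trainable convolutional networks that also expose internal
activations and their gradients (for class-activation mapping) — this module
provides exactly that surface on plain numpy: Conv2d (im2col + BLAS),
InstanceNorm, ReLU/LeakyReLU/Sigmoid/Tanh, max pooling, nearest-neighbor
upsampling, global average pooling, a linear head, Adam, and a Sequential
container. Arrays are NCHW float64. Everything is deterministic given the
initialization seed.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, oh, ow, kh, kw),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
    )
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), (n, c, h, w, oh, ow)


def _col2im(cols: np.ndarray, shape: tuple, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w, oh, ow = shape
    x = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, oh, ow, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += cols[
                :, :, :, :, i, j
            ].transpose(0, 3, 1, 2)
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1, pad: int | None = None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.normal(0, scale, size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols, self._shape = _im2col(x, self.k, self.k, self.stride, self.pad)
        n, _, _, _, oh, ow = self._shape
        out = self._cols @ self.W.reshape(len(self.W), -1).T + self.b
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oc, oh, ow = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, oc)
        self.grads[0][...] = (g.T @ self._cols).reshape(self.W.shape)
        self.grads[1][...] = g.sum(axis=0)
        dcols = g @ self.W.reshape(oc, -1)
        return _col2im(dcols, self._shape, self.k, self.k, self.stride, self.pad)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization with learnable affine terms."""

    def __init__(self, ch: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mu = x.mean(axis=(2, 3), keepdims=True)
        self.var = x.var(axis=(2, 3), keepdims=True)
        self.xhat = (x - self.mu) / np.sqrt(self.var + self.eps)
        return self.gamma[None, :, None, None] * self.xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        m = h * w
        self.grads[0][...] = (grad * self.xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = grad.sum(axis=(0, 2, 3))
        gx = grad * self.gamma[None, :, None, None]
        inv = 1.0 / np.sqrt(self.var + self.eps)
        return inv * (gx - gx.mean(axis=(2, 3), keepdims=True) - self.xhat * (gx * self.xhat).mean(axis=(2, 3), keepdims=True))


class ReLU(Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        self.mask = x > 0
        return np.where(self.mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self.mask, grad, self.slope * grad)


class Sigmoid(Layer):
    def forward(self, x):
        self.y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self.y

    def backward(self, grad):
        return grad * self.y * (1 - self.y)


class Tanh(Layer):
    def forward(self, x):
        self.y = np.tanh(x)
        return self.y

    def backward(self, grad):
        return grad * (1 - self.y**2)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even spatial dims required)."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        self.x_shape = x.shape
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self.argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, oh, ow = grad.shape
        out = np.zeros((n, c, oh, ow, 4))
        np.put_along_axis(out, self.argmax[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(self.x_shape)


class NearestUpsample(Layer):
    """2x nearest-neighbor upsampling (checkerboard-free alternative to
    transposed convolution when followed by a convolution)."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    """Inverted dropout; active only when ``training`` is set."""

    def __init__(self, rate: float = 0.5, seed: int = 0):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(seed)
        self.training = False

    def forward(self, x):
        if not self.training or self.rate <= 0:
            self.mask = None
            return x
        self.mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class GlobalAvgPool(Layer):
    def forward(self, x):
        self.in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self.in_shape
        return np.broadcast_to(grad[:, :, None, None], self.in_shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self.x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @params.setter
    def params(self, value):  # Layer.__init__ compatibility
        pass

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    @grads.setter
    def grads(self, value):
        pass

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean (optionally class-weighted) cross-entropy loss and its gradient."""
    p = softmax(logits)
    n = len(labels)
    w = np.ones(n) if weights is None else weights[labels]
    loss = float(-(w * np.log(p[np.arange(n), labels] + 1e-12)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad
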