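"""Minimal convolutional-network engine (numpy, CPU).

Just enough machinery to train the package's compact image classifier from
scratch: im2col convolution, 2x2 max pooling, average-pool downsampling,
fully connected layers, ReLU, softmax cross-entropy and SGD with momentum.
Everything is deterministic given the seeded generator used for weight
initialization and batch shuffling.

Data layout is NCHW float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, oh*ow, C*kh*kw) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw), oh, ow


def _col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, ...],
    kh: int, kw: int, stride: int, pad: int,
    oh: int, ow: int,
) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for a in range(kh):
        for b in range(kw):
            dxp[:, :, a:a + stride * oh:stride, b:b + stride * ow:stride] += d[..., a, b]
    if pad:
        return dxp[:, :, pad:pad + h, pad:pad + w]
    return dxp


class Conv2D(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int,
                 rng: np.random.Generator, stride: int = 1) -> None:
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = rng.normal(0, scale, (out_ch, in_ch, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.kernel, self.pad, self.stride = kernel, pad, stride
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        out = cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        return out.transpose(0, 2, 1).reshape(x.shape[0], -1, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oc, oh, ow = grad.shape
        g = grad.reshape(n, oc, oh * ow).transpose(0, 2, 1)  # (N, P, oc)
        self.dw = np.einsum("npo,npk->ok", g, self._cols).reshape(self.w.shape)
        self.db = g.sum(axis=(0, 1))
        dcols = g @ self.w.reshape(oc, -1)
        return _col2im(dcols, self._x_shape, self.kernel, self.kernel,
                       self.stride, self.pad, self._oh, self._ow)

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties resolve to the first maximum."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        d = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(d, self._idx[..., None], grad[..., None], axis=-1)
        d = d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(n, c, h, w)


class AvgPoolK(Layer):
    """k x k average pooling, stride k — used to downsample the input raster."""

    def __init__(self, k: int) -> None:
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        self._in_shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.k
        g = grad / (k * k)
        return np.repeat(np.repeat(g, k, axis=2), k, axis=3)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params_grads(self):
        return [pg for layer in self.layers for pg in layer.params_grads()]


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), targets] + 1e-12).mean())
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


class SGD:
    def __init__(self, net: Sequential, lr: float, momentum: float = 0.9) -> None:
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p) for p, _ in net.params_grads()]

    def step(self) -> None:
        for v, (p, g) in zip(self._vel, self.net.params_grads()):
            v *= self.momentum
            v -= self.lr * g
            p += v


def small_cnn(input_hw: tuple[int, int], n_classes: int,
              rng: np.random.Generator, downsample: int = 4) -> Sequential:
    """Compact two-conv-block classifier trained from scratch.

    The sparse fixation rasters carry their signal in coarse spatial layout,
    so the input is average-pooled by ``downsample`` first; two small
    convolution blocks then feed a narrow fully connected head.
    """
    h, w = input_hw
    h2, w2 = h // downsample, w // downsample
    fh, fw = h2 // 4, w2 // 4  # after two 2x2 max pools
    return Sequential([
        AvgPoolK(downsample),
        Conv2D(3, 8, kernel=5, pad=2, rng=rng),
        ReLU(),
        MaxPool2(),
        Conv2D(8, 16, kernel=3, pad=1, rng=rng),
        ReLU(),
        MaxPool2(),
        Flatten(),
        Linear(fh * fw * 16, 32, rng),
        ReLU(),
        Linear(32, n_classes, rng),
    ])
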