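"""Minimal 1-D neural-network layers in numpy with explicit backprop.

No deep-learning framework is available in the runtime environment, so the
layers needed by the bottleneck-residual classifier are implemented here:
1-D convolution (pointwise, depthwise and full), batch normalization,
ReLU6, max pooling, global average pooling and fully connected layers,
each with forward and backward passes over (batch, channels, length)
arrays.  Parameters and gradients are exposed as flat lists so the
momentum-SGD optimizer can treat every layer uniformly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1d", "DepthwiseConv1d", "BatchNorm1d", "ReLU6",
    "MaxPool1d", "GlobalAvgPool1d", "Linear", "Flatten", "Sequential",
    "Bottleneck1d", "softmax", "cross_entropy_with_grad",
]


class Layer:
    """Base class: stateless unless it declares params/grads."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def set_training(self, mode: bool) -> None:
        self.training = mode


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding windows over the padded length axis: (B, C, L, k)."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    return np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)


class Conv1d(Layer):
    """Same-padded 1-D convolution, stride 1 (kernel 1 = pointwise)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for same padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.params = [self.w]
        self.b = None
        if bias:
            self.b = np.zeros(c_out)
            self.params.append(self.b)
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = _windows(x, self.kernel)  # (B, Cin, L, k)
        self._in_shape = x.shape
        y = np.einsum("bclk,ock->bol", self._win, self.w, optimize=True)
        if self.b is not None:
            y += self.b[None, :, None]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("bclk,bol->ock", self._win, gy,
                                       optimize=True)
        if self.b is not None:
            self.grads[1][...] = gy.sum(axis=(0, 2))
        # full correlation of gy with flipped kernels
        gwin = _windows(gy, self.kernel)  # (B, Cout, L, k)
        gx = np.einsum("bolk,ock->bcl", gwin, self.w[:, :, ::-1],
                       optimize=True)
        return gx


class DepthwiseConv1d(Layer):
    """Per-channel temporal convolution (no channel mixing), stride 1."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for same padding")
        self.channels, self.kernel = channels, kernel
        scale = np.sqrt(2.0 / kernel)
        self.w = rng.normal(0.0, scale, size=(channels, kernel))
        self.params = [self.w]
        self.b = None
        if bias:
            self.b = np.zeros(channels)
            self.params.append(self.b)
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = _windows(x, self.kernel)  # (B, C, L, k)
        y = np.einsum("bclk,ck->bcl", self._win, self.w, optimize=True)
        if self.b is not None:
            y += self.b[None, :, None]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("bclk,bcl->ck", self._win, gy,
                                       optimize=True)
        if self.b is not None:
            self.grads[1][...] = gy.sum(axis=(0, 2))
        gwin = _windows(gy, self.kernel)
        return np.einsum("bclk,ck->bcl", gwin, self.w[:, ::-1], optimize=True)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._istd[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = (gy * self._xhat).sum(axis=(0, 2))
        self.grads[1][...] = gy.sum(axis=(0, 2))
        if not self.training:
            return gy * (self.gamma * self._istd)[None, :, None]
        m = gy.shape[0] * gy.shape[2]
        gxhat = gy * self.gamma[None, :, None]
        gsum = gxhat.sum(axis=(0, 2))[None, :, None]
        gdot = (gxhat * self._xhat).sum(axis=(0, 2))[None, :, None]
        return (self._istd[None, :, None] / m
                * (m * gxhat - gsum - self._xhat * gdot))


class ReLU6(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling, kernel = stride = 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, n = x.shape
        if n % 2:  # drop the odd tail, as stride-2 pooling does
            x = x[:, :, : n - 1]
            n -= 1
        xr = x.reshape(b, c, n // 2, 2)
        self._arg = xr.argmax(axis=3)
        self._in_len = n
        return xr.max(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, half = gy.shape
        gx = np.zeros((b, c, half, 2))
        np.put_along_axis(gx, self._arg[..., None], gy[..., None], axis=3)
        return gx.reshape(b, c, self._in_len)


class GlobalAvgPool1d(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.repeat(gy[:, :, None], self._len, axis=2) / self._len


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = gy.T @ self._x
        self.grads[1][...] = gy.sum(axis=0)
        return gy @ self.w


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for layer in self.layers:
            layer.set_training(mode)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.iter_layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.iter_layers() for g in layer.grads]

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            elif isinstance(layer, Bottleneck1d):
                yield from layer.body.iter_layers()
            else:
                yield layer


class Bottleneck1d(Layer):
    """Inverted residual block: pwconv-expand, dwconv, pwconv-project.

    Each convolution is followed by batch normalization; ReLU6 after the
    first two, linear after the projection.  The identity shortcut is added
    when input and output widths match.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 expansion: int = 4, kernel: int = 3):
        super().__init__()
        hidden = c_in * expansion
        self.residual = c_in == c_out
        self.body = Sequential(
            Conv1d(c_in, hidden, 1, rng, bias=False), BatchNorm1d(hidden),
            ReLU6(),
            DepthwiseConv1d(hidden, kernel, rng, bias=False),
            BatchNorm1d(hidden), ReLU6(),
            Conv1d(hidden, c_out, 1, rng, bias=False), BatchNorm1d(c_out),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.body.forward(x)
        return y + x if self.residual else y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = self.body.backward(gy)
        return gx + gy if self.residual else gx

    def set_training(self, mode: bool) -> None:
        self.training = mode
        self.body.set_training(mode)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray,
                            labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
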