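"""Minimal NumPy layer framework with explicit forward/backward passes.

Tensors are NCHW float arrays. Every layer caches what its backward pass
needs during forward; ``backward(grad_out)`` returns the gradient with
respect to the input and accumulates parameter gradients in-place on
:class:`Param` objects. No external deep-learning framework is used so
that training runs deterministically on a bare scientific Python stack.
"""

from __future__ import annotations

from typing import Callable, Iterator

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "AvgPool2d",
    "Sequential",
    "SGD",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    """Base class: children discovered via attributes for traversal."""

    training: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    __call__ = forward

    def children(self) -> Iterator[tuple[str, "Layer"]]:
        for name, val in vars(self).items():
            if isinstance(val, Layer):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Layer):
                        yield f"{name}.{i}", item

    def named_params(self, prefix: str = "") -> Iterator[tuple[str, Param]]:
        for name, val in vars(self).items():
            if isinstance(val, Param):
                yield prefix + name, val
        for cname, child in self.children():
            yield from child.named_params(prefix + cname + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for cname, child in self.children():
            yield from child.named_buffers(prefix + cname + ".")

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_params()]

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for _, child in self.children():
            child.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    """2-D convolution, stride 1, 'same' zero padding for odd kernels."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        if kernel_size % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(_he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in, dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype))
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # computed as a sum of k*k shifted channel matmuls: cheaper in
        # memory traffic than im2col for the narrow layers used here
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, p = self.kernel_size, self.kernel_size // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # channels-last once; shifted slices of this feed every tap
        xl = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (N, H+2p, W+2p, C)
        y = np.empty((n, h, w, self.out_channels), dtype=x.dtype)
        y[...] = self.bias.data
        wmats = self.weight.data.transpose(2, 3, 1, 0)  # (k, k, Cin, Cout)
        for i in range(k):
            for j in range(k):
                y += xl[:, i : i + h, j : j + w] @ wmats[i, j]
        self._cache = (xl, (n, h, w))
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xl, (n, h, w) = self._cache
        k, p = self.kernel_size, self.kernel_size // 2
        gy = np.ascontiguousarray(grad_out.transpose(0, 2, 3, 1))  # (N, H, W, O)
        gy2 = gy.reshape(-1, self.out_channels)
        self.bias.grad += gy2.sum(axis=0)
        wmats = self.weight.data.transpose(2, 3, 1, 0)  # (k, k, Cin, Cout)
        gxl = np.zeros_like(xl)
        for i in range(k):
            for j in range(k):
                xs = xl[:, i : i + h, j : j + w].reshape(-1, self.in_channels)
                self.weight.grad[:, :, i, j] += (gy2.T @ xs)
                gxl[:, i : i + h, j : j + w] += (gy2 @ wmats[i, j].T).reshape(
                    n, h, w, self.in_channels
                )
        gxp = gxl.transpose(0, 3, 1, 2)
        return np.ascontiguousarray(gxp[:, :, p : p + h, p : p + w] if p else gxp)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Param(_he_init(rng, (in_channels, out_channels, 2, 2), in_channels, dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype))
        self._cache: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        y = np.empty((n, self.out_channels, 2 * h, 2 * w), dtype=x.dtype)
        for a in (0, 1):
            for b in (0, 1):
                y[:, :, a::2, b::2] = np.tensordot(
                    x, self.weight.data[:, :, a, b], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        y += self.bias.data[None, :, None, None]
        self._cache = x
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._cache
        gx = np.zeros_like(x)
        for a in (0, 1):
            for b in (0, 1):
                g_ab = grad_out[:, :, a::2, b::2]
                self.weight.grad[:, :, a, b] += np.tensordot(
                    x, g_ab, axes=([0, 2, 3], [0, 2, 3])
                )
                gx += np.tensordot(g_ab, self.weight.data[:, :, a, b], axes=([1], [1])).transpose(
                    0, 3, 1, 2
                )
        self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        return gx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learnable affine transform."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        g_xhat = grad_out * self.gamma.data[None, :, None, None]
        if not self.training:
            return g_xhat * inv_std[None, :, None, None]
        n, _, h, w = grad_out.shape
        m = n * h * w
        sum_g = g_xhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gx = (g_xhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv_std[None, :, None, None] / m) * (m * g_xhat - sum_g - xhat * sum_gx)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # clamp pre-activations: sigmoid saturates far below float precision
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._y * (1.0 - self._y)


class AvgPool2d(Layer):
    """2x2 average pooling with stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"AvgPool2d needs even spatial dims, got {h}x{w}")
        self._in_shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = np.repeat(np.repeat(grad_out, 2, axis=2), 2, axis=3) / 4.0
        return g.astype(grad_out.dtype)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
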