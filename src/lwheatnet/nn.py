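"""Minimal NumPy neural-network layer engine.

Implements the handful of layer types the seed-classification network needs
(2-D convolutions, batch normalisation, pooling, dropout, a linear head and a
1-D cross-channel convolution) with explicit forward and backward passes.
Arrays are laid out NCHW.  Each layer caches what its backward pass needs on
``forward`` and accumulates parameter gradients on ``backward``; an optimiser
reads ``Parameter.grad`` and writes ``Parameter.data``.

The engine is deliberately small: no autograd graph, no lazy shapes.  Layers
compose through explicit ``Module`` containers whose ``backward`` mirrors
their ``forward`` control flow.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dropout",
    "Linear",
    "ChannelConv1d",
    "softmax",
    "kaiming_normal",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return int(self.data.size)


def kaiming_normal(rng: np.random.Generator, shape, fan_out: int, dtype=np.float32):
    """He-style fan-out normal initialisation for conv/linear weights."""
    std = np.sqrt(2.0 / fan_out)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Module:
    """Base class: parameter/buffer discovery by attribute walking."""

    def named_parameters(self, prefix: str = ""):
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if prefix else name
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(full + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if prefix else name
            if isinstance(attr, Module):
                yield from attr.named_buffers(full + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif name.startswith("running_") and isinstance(attr, np.ndarray):
                yield full, attr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def astype(self, dtype) -> "Module":
        """Cast all parameters and running buffers in place (e.g. to float64
        for finite-difference checks)."""
        for _, p in self.named_parameters():
            p.data = p.data.astype(dtype)
            p.grad = p.grad.astype(dtype)
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                attr.astype(dtype)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.astype(dtype)
            elif name.startswith("running_") and isinstance(attr, np.ndarray):
                setattr(self, name, attr.astype(dtype))
        return self

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Convolutions.  Implemented as a loop over the k*k kernel offsets; each
# offset contributes one (C_out x C_in) matmul over a strided view, which
# keeps memory flat (no im2col buffer) and is fast for the 1x1 convolutions
# that dominate this architecture.
# ---------------------------------------------------------------------------


class Conv2d(Module):
    """Standard 2-D convolution, NCHW, zero padding.

    ``padding=None`` means "same" at stride 1 (k // 2), which also realises
    the floor-division shape walk at stride 2 used throughout the network
    (224 -> 112 -> 56 for a 3x3 stride-2 conv).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None, bias: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if kernel % 2 == 0:
            raise ValueError(f"even kernel size {kernel} is not supported")
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_out = out_channels * kernel * kernel
        self.weight = Parameter(
            kaiming_normal(rng, (out_channels, in_channels, kernel, kernel), fan_out, dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, p = self.kernel, self.stride, self.padding
        ho, wo = self.out_shape(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._cache = (xp, x.shape, ho, wo)
        wmat = self.weight.data
        out = np.zeros((n, ho, wo, self.out_channels), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                # (N,Cin,Ho,Wo) x (Cout,Cin) -> (N,Ho,Wo,Cout)
                out += np.tensordot(patch, wmat[:, :, i, j], axes=([1], [1]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        return out

    def backward(self, dy):
        xp, xshape, ho, wo = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))  # N,Ho,Wo,Cout
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                self.weight.grad[:, :, i, j] += np.tensordot(
                    dyt, patch, axes=([0, 1, 2], [0, 2, 3]))
                contrib = np.tensordot(dyt, self.weight.data[:, :, i, j],
                                       axes=([3], [0]))  # N,Ho,Wo,Cin
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += contrib.transpose(0, 3, 1, 2)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class DepthwiseConv2d(Module):
    """Per-channel (depthwise) k x k convolution; in/out channels equal."""

    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if kernel % 2 == 0:
            raise ValueError(f"even kernel size {kernel} is not supported")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2
        self.weight = Parameter(
            kaiming_normal(rng, (channels, kernel, kernel), kernel * kernel, dtype))

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        k, s, p = self.kernel, self.stride, self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._cache = (xp, ho, wo)
        out = np.zeros((n, c, ho, wo), dtype=x.dtype)
        wmat = self.weight.data
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                out += wmat[None, :, i, j, None, None] * patch
        return out

    def backward(self, dy):
        xp, ho, wo = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                self.weight.grad[:, i, j] += (dy * patch).sum(axis=(0, 2, 3))
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += (
                    self.weight.data[None, :, i, j, None, None] * dy)
        return dxp[:, :, p:-p, p:-p] if p else dxp


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel; eps 1e-5, running-stat
    momentum 0.1.  The running statistics are seeded from the first training
    batch (rather than the arbitrary 0/1 initial values) so that evaluation
    mode is meaningful even after very short runs."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.running_count = np.zeros(1, dtype=dtype)

    def forward(self, x, train: bool = False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum if self.running_count[0] > 0 else 1.0
            self.running_count[0] = 1.0
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, train)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy):
        xhat, ivar, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        if not train:
            return dxhat * ivar[None, :, None, None]
        n, _, h, w = dy.shape
        m = n * h * w
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (ivar[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ReLU(Module):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Module):
    def forward(self, x, train: bool = False):
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


class MaxPool2d(Module):
    """Max pooling with zero-area (-inf) padding; defaults match the 3x3
    stride-2 pool of the network stem (112 -> 56)."""

    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        neg = np.finfo(x.dtype).min
        xp = np.full((n, c, h + 2 * p, w + 2 * p), neg, dtype=x.dtype)
        xp[:, :, p:p + h, p:p + w] = x
        stack = np.stack([
            xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
            for i in range(k) for j in range(k)
        ])
        arg = stack.argmax(axis=0)
        self._cache = (arg, x.shape, ho, wo)
        return np.take_along_axis(stack, arg[None], axis=0)[0]

    def backward(self, dy):
        arg, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.kernel, self.stride, self.padding
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            mask = arg == idx
            dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dy * mask
        return dxp[:, :, p:p + h, p:p + w]


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dropout(Module):
    """Inverted dropout; identity at evaluation time.  The RNG is attached by
    whoever owns the training loop (``rng`` attribute)."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, train: bool = False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng(0)
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        # Kaiming fan-out, matching the convolutions.  The resulting head
        # starts with large logits, whose large early errors speed up the
        # first epochs under the EMA-momentum optimiser (an implicit warmup).
        self.weight = Parameter(kaiming_normal(rng, (out_features, in_features),
                                               out_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x, train: bool = False):
        self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y = y + self.bias.data
        return y

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class ChannelConv1d(Module):
    """1-D convolution across the channel axis of a (N, C) descriptor with a
    single shared kernel and zero padding — the cross-channel interaction of
    efficient channel attention.  No bias (standard ECA convention)."""

    def __init__(self, kernel: int, dtype=np.float32):
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
        self.kernel = kernel
        self.weight = Parameter(np.full(kernel, 1.0 / kernel, dtype=dtype))

    def forward(self, x, train: bool = False):
        n, c = x.shape
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p)))
        self._xp = xp
        out = np.zeros_like(x)
        for j in range(k):
            out += self.weight.data[j] * xp[:, j:j + c]
        return out

    def backward(self, dy):
        xp = self._xp
        n, c = dy.shape
        k = self.kernel
        p = k // 2
        dxp = np.zeros_like(xp)
        for j in range(k):
            self.weight.grad[j] += (dy * xp[:, j:j + c]).sum()
            dxp[:, j:j + c] += self.weight.data[j] * dy
        return dxp[:, p:p + c] if p else dxp


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
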