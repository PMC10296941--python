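"""Minimal numpy neural-network layers with manual backpropagation.

Implements exactly what the two classifier branches need: 3D and 2D
convolution, batch normalization, average / max pooling, dense layers,
ReLU and a softmax cross-entropy head, plus SGD with momentum.  All
randomness flows through an explicit ``numpy.random.Generator`` so that
training is bit-reproducible given a seed.

Convolutions are evaluated per kernel offset: for each of the
``kS*kH*kW`` offsets a strided view of the padded input is contracted
with the corresponding weight slice via BLAS (``tensordot``).  This
keeps memory at one padded copy of the input instead of a full im2col
buffer, and the same decomposition yields the weight and input
gradients.  Computation is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "AvgPool3d",
    "MaxPool2d",
    "Flatten",
    "Dense",
    "Network",
    "SGD",
    "softmax",
    "cross_entropy",
]

_DT = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), targets], 1e-30)).mean()
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), (grad / n).astype(_DT)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "trainable", "name")

    def __init__(self, data: np.ndarray, name: str = "", trainable: bool = True):
        self.data = np.asarray(data, dtype=_DT)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable
        self.name = name


class Layer:
    block: int = 0  # transfer-learning block tag; 0 = untagged/head

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _triple(v) -> tuple[int, ...]:
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v),) * 3


def _pair(v) -> tuple[int, ...]:
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v),) * 2


class _ConvNd(Layer):
    """Shared offset-decomposed convolution for 2 or 3 spatial axes."""

    def __init__(self, c_in, c_out, kernel, stride, padding, ndim, rng, name=""):
        self.ndim = ndim
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = c_in * int(np.prod(kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, *kernel))
        self.w = Param(w, name=f"{name}.w")
        self.b = Param(np.zeros(c_out), name=f"{name}.b")
        self._xp: np.ndarray | None = None
        self._out_extents: tuple[int, ...] | None = None

    def params(self):
        return [self.w, self.b]

    def out_extents(self, in_extents):
        return tuple(
            (n + 2 * p - k) // s + 1
            for n, k, s, p in zip(in_extents, self.kernel, self.stride, self.padding)
        )

    def _pad(self, x):
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        if not any(self.padding):
            return x
        return np.pad(x, pad)

    def _offsets(self):
        return np.ndindex(*self.kernel)

    def _view(self, xp, off, out_ext):
        sl = [slice(None), slice(None)]
        for o, s, n in zip(off, self.stride, out_ext):
            sl.append(slice(o, o + s * n, s))
        return xp[tuple(sl)]

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=_DT)
        out_ext = self.out_extents(x.shape[2:])
        if min(out_ext) < 1:
            raise ValueError(f"kernel {self.kernel} does not fit input {x.shape[2:]}")
        xp = self._pad(x)
        n, c_out = x.shape[0], self.w.data.shape[0]
        out = np.empty((n, c_out, *out_ext), dtype=_DT)
        out[:] = self.b.data.reshape((1, c_out) + (1,) * self.ndim)
        for off in self._offsets():
            patch = self._view(xp, off, out_ext)  # (N, Cin, *out_ext)
            wk = self.w.data[(slice(None), slice(None)) + off]  # (Cout, Cin)
            contrib = np.tensordot(patch, wk, axes=([1], [1]))  # (N, *out, Cout)
            out += np.moveaxis(contrib, -1, 1)
        self._xp, self._out_extents = xp, out_ext
        return out

    def backward(self, grad):
        xp, out_ext = self._xp, self._out_extents
        grad = np.ascontiguousarray(grad, dtype=_DT)
        sum_axes = (0, *range(2, 2 + self.ndim))
        if self.b.trainable:
            self.b.grad += grad.sum(axis=sum_axes)
        gxp = np.zeros_like(xp)
        for off in self._offsets():
            patch = self._view(xp, off, out_ext)
            if self.w.trainable:
                gw = np.tensordot(grad, patch, axes=(sum_axes, sum_axes))
                self.w.grad[(slice(None), slice(None)) + off] += gw
            wk = self.w.data[(slice(None), slice(None)) + off]
            gpatch = np.tensordot(grad, wk, axes=([1], [0]))  # (N, *out, Cin)
            self._view(gxp, off, out_ext)[:] += np.moveaxis(gpatch, -1, 1)
        self._xp = None
        if not any(self.padding):
            return gxp
        sl = [slice(None), slice(None)] + [
            slice(p, gxp.shape[i + 2] - p) for i, p in enumerate(self.padding)
        ]
        return gxp[tuple(sl)]


class Conv3d(_ConvNd):
    """3D convolution over (spectral, height, width) feature maps."""

    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, rng=None, name="conv3d"):
        rng = rng or np.random.default_rng(0)
        super().__init__(
            c_in, c_out, _triple(kernel), _triple(stride), _triple(padding), 3, rng, name
        )


class Conv2d(_ConvNd):
    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, rng=None, name="conv2d"):
        rng = rng or np.random.default_rng(0)
        super().__init__(
            c_in, c_out, _pair(kernel), _pair(stride), _pair(padding), 2, rng, name
        )


class BatchNorm(Layer):
    """Per-channel batch normalization for (N, C, ...) tensors."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, name="bn"):
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train):
        axes = (0, *range(2, x.ndim))
        shape = self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_sd.reshape(shape)
        if train:
            self._cache = (xhat, inv_sd, axes, shape)
        return (self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)).astype(_DT)

    def backward(self, grad):
        xhat, inv_sd, axes, shape = self._cache
        self._cache = None
        m = grad.size / grad.shape[1]
        if self.gamma.trainable:
            self.gamma.grad += (grad * xhat).sum(axis=axes)
        if self.beta.trainable:
            self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.data.reshape(shape)
        gsum = g.sum(axis=axes, keepdims=True)
        gxsum = (g * xhat).sum(axis=axes, keepdims=True)
        dx = (g - gsum / m - xhat * gxsum / m) * inv_sd.reshape(shape)
        return dx.astype(_DT)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool3d(Layer):
    """Average pooling with kernel == stride, floor mode.

    Axes shorter than the kernel are pooled with the kernel clipped to
    the axis extent, so degenerate 1-px axes pass through unchanged.
    """

    def __init__(self, kernel=2):
        self.k = _triple(kernel)

    def forward(self, x, train):
        n, c, s, h, w = x.shape
        ks, kh, kw = (min(k, e) for k, e in zip(self.k, (s, h, w)))
        self._keff = (ks, kh, kw)
        so, ho, wo = s // ks, h // kh, w // kw
        self._in_shape = x.shape
        cropped = x[:, :, : so * ks, : ho * kh, : wo * kw]
        r = cropped.reshape(n, c, so, ks, ho, kh, wo, kw)
        return r.mean(axis=(3, 5, 7))

    def backward(self, grad):
        n, c, s, h, w = self._in_shape
        ks, kh, kw = self._keff
        so, ho, wo = grad.shape[2:]
        g = np.zeros(self._in_shape, dtype=_DT)
        expanded = (
            grad[:, :, :, None, :, None, :, None]
            / (ks * kh * kw)
        )
        g[:, :, : so * ks, : ho * kh, : wo * kw] = np.broadcast_to(
            expanded, (n, c, so, ks, ho, kh, wo, kw)
        ).reshape(n, c, so * ks, ho * kh, wo * kw)
        return g


class MaxPool2d(Layer):
    """2x2 (default) max pooling with kernel == stride, floor mode."""

    def __init__(self, kernel=2):
        self.k = _pair(kernel)

    def forward(self, x, train):
        n, c, h, w = x.shape
        kh, kw = (min(k, e) for k, e in zip(self.k, (h, w)))
        self._keff = (kh, kw)
        ho, wo = h // kh, w // kw
        self._in_shape = x.shape
        r = x[:, :, : ho * kh, : wo * kw].reshape(n, c, ho, kh, wo, kw)
        flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, kh * kw)
        self._arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._in_shape
        kh, kw = self._keff
        ho, wo = grad.shape[2:]
        flat = np.zeros((n, c, ho, wo, kh * kw), dtype=_DT)
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        g = np.zeros(self._in_shape, dtype=_DT)
        g[:, :, : ho * kh, : wo * kw] = (
            flat.reshape(n, c, ho, wo, kh, kw).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho * kh, wo * kw)
        )
        return g


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None, name="dense"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w = Param(w, name=f"{name}.w")
        self.b = Param(np.zeros(n_out), name=f"{name}.b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, grad):
        if self.w.trainable:
            self.w.grad += self._x.T @ grad
        if self.b.trainable:
            self.b.grad += grad.sum(axis=0)
        self._x = None
        return grad @ self.w.data.T


class Network:
    """A plain sequential stack producing class logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def state(self) -> list[np.ndarray]:
        tensors = [p.data.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                tensors += [layer.running_mean.copy(), layer.running_var.copy()]
        return tensors


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if not p.trainable:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v
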