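"""Layers: dense, 3D conv / transposed conv, batch norm, pooling, activations."""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter
from . import functional as F


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.W = Parameter(_kaiming(rng, in_features, (in_features, out_features)))
        self.b = Parameter(np.zeros(out_features)) if bias else None
        self._x = None

    def forward(self, x, train: bool = False):
        self._x = x
        out = x @ self.W.data
        if self.b is not None:
            out = out + self.b.data
        return out

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.W.data.T


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.k, self.stride, self.pad = k, stride, pad
        fan_in = cin * k ** 3
        self.W = Parameter(_kaiming(rng, fan_in, (fan_in, cout)))
        self.b = Parameter(np.zeros(cout)) if bias else None
        self._cache = None
        self._is_input_layer = False  # skip the data gradient when set

    def forward(self, x, train: bool = False):
        out, self._cache = F.conv3d_forward(
            x, self.W.data, self.b.data if self.b is not None else None,
            self.k, self.stride, self.pad)
        return out

    def backward(self, grad):
        dx, dw, db = F.conv3d_backward(
            grad, self.W.data, self._cache, self.k, self.stride, self.pad,
            need_dx=not self._is_input_layer)
        self.W.grad += dw
        if self.b is not None:
            self.b.grad += db
        return dx


class ConvTranspose3d(Module):
    """Transposed conv as a per-kernel-offset scatter from the input grid.

    Output size follows (d - 1) * stride - 2 * pad + k + output_padding.
    Each kernel offset (i, j, k) contributes ``x contracted with W[..., i, j, k]``
    to a strided slab of the output, so all work stays on the small input grid
    instead of the zero-stuffed upsampled one.  Weights are stored
    (cin, k, k, k, cout).
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 output_padding, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.k, self.stride, self.pad = k, stride, pad
        op = np.broadcast_to(np.asarray(output_padding), (3,))
        self.output_padding = tuple(int(v) for v in op)
        fan_in = cin * k ** 3
        self.W = Parameter(_kaiming(rng, fan_in, (cin, k, k, k, cout)))
        self.b = Parameter(np.zeros(cout)) if bias else None
        self._x = None

    def _out_shape(self, in_spatial):
        s, p, k = self.stride, self.pad, self.k
        return tuple((d - 1) * s - 2 * p + k + o
                     for d, o in zip(in_spatial, self.output_padding))

    def forward(self, x, train: bool = False):
        self._x = x
        n = x.shape[0]
        d, h, w = x.shape[2:]
        s, p, k = self.stride, self.pad, self.k
        out_sp = self._out_shape((d, h, w))
        # scatter into a padded buffer (channel-last for contiguous writes)
        buf = np.zeros((n,) + tuple((dd - 1) * s + k for dd in (d, h, w))
                       + (self.cout,))
        for i in range(k):
            for j in range(k):
                for kk in range(k):
                    contrib = np.tensordot(x, self.W.data[:, i, j, kk, :],
                                           axes=(1, 0))  # (n, d, h, w, cout)
                    buf[:, i:i + s * d:s, j:j + s * h:s, kk:kk + s * w:s] += contrib
        out = buf[:, p:p + out_sp[0], p:p + out_sp[1], p:p + out_sp[2]]
        out = np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))
        if self.b is not None:
            out += self.b.data[None, :, None, None, None]
        return out

    def backward(self, grad):
        x = self._x
        n = x.shape[0]
        d, h, w = x.shape[2:]
        s, p, k = self.stride, self.pad, self.k
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        # pad the output gradient so every scatter slab gathers in-bounds
        gcl = np.ascontiguousarray(grad.transpose(0, 2, 3, 4, 1))
        gp = np.pad(gcl, ((0, 0),) + tuple(
            (p, (dd - 1) * s + k - p - o)
            for dd, o in zip((d, h, w), (grad.shape[2], grad.shape[3],
                                         grad.shape[4])))
            + ((0, 0),))
        dx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                for kk in range(k):
                    slab = gp[:, i:i + s * d:s, j:j + s * h:s, kk:kk + s * w:s]
                    # dW[ci, i, j, kk, co] = sum_n,dhw x * slab
                    self.W.grad[:, i, j, kk, :] += np.tensordot(
                        x, slab, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
                    dx += np.tensordot(slab, self.W.data[:, i, j, kk, :],
                                       axes=(4, 1)).transpose(0, 4, 1, 2, 3)
        return dx


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def forward(self, x, train: bool = False):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mean)
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma.data[None, :, None, None, None] * xhat \
            + self.beta.data[None, :, None, None, None]

    def backward(self, grad):
        xhat, inv, was_train = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.data[None, :, None, None, None]
        if not was_train:
            return grad * g * inv[None, :, None, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        gsum = grad.sum(axis=axes, keepdims=True)
        gxsum = (grad * xhat).sum(axis=axes, keepdims=True)
        return (g * inv[None, :, None, None, None] / m) * (
            m * grad - gsum - xhat * gxsum)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x, train: bool = False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class MaxPool3d(Module):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train: bool = False):
        from numpy.lib.stride_tricks import sliding_window_view

        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3,
                    constant_values=-np.inf)
        v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        v = v[:, :, ::s, ::s, ::s]
        n, c, do, ho, wo = v.shape[:5]
        flat = np.ascontiguousarray(v).reshape(n, c, do, ho, wo, k ** 3)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, xp.shape, (do, ho, wo))
        return out

    def backward(self, grad):
        idx, x_shape, xp_shape, out_sp = self._cache
        k, s, p = self.k, self.stride, self.pad
        n, c = x_shape[0], x_shape[1]
        do, ho, wo = out_sp
        a, rem = np.divmod(idx, k * k)
        b, cc = np.divmod(rem, k)
        ni, ci, di, hi, wi = np.indices((n, c, do, ho, wo), sparse=False)
        dd = di * s + a
        hh = hi * s + b
        ww = wi * s + cc
        dxp = np.zeros(xp_shape)
        np.add.at(dxp, (ni, ci, dd, hh, ww), grad)
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class GlobalAvgPool3d(Module):
    """(N, C, D, H, W) -> (N, C)."""

    def __init__(self):
        super().__init__()
        self._spatial = None

    def forward(self, x, train: bool = False):
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        d, h, w = self._spatial
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(
            grad[:, :, None, None, None], grad.shape + (d, h, w)) * scale


class Flatten(Module):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Module):
    def __init__(self, target):
        super().__init__()
        self.target = tuple(target)
        self._shape = None

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)
        for i, m in enumerate(modules):
            self._children[str(i)] = m

    def forward(self, x, train: bool = False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, grad):
        for m in reversed(self.modules):
            grad = m.backward(grad)
        return grad
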