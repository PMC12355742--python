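"""Composite blocks: basic 3D residual block, squeeze-and-excite, DAFT.

The squeeze-and-excite block recalibrates channels with a gating vector
computed from globally pooled features.  The DAFT block applies a per-channel
affine transform (scale, shift) to a feature map, with the scale and shift
predicted from the pooled feature map concatenated with a tabular vector; its
final dense layer is zero-initialized and the scale is offset by one, so the
block is an exact identity at initialization.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter
from .layers import BatchNorm3d, Conv3d, Dense, ReLU, Sequential


class ResidualBlock(Module):
    """conv3-bn-relu-conv3-bn plus a (projected) shortcut, then relu."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, 3, stride, 1, rng, bias=False)
        self.bn1 = BatchNorm3d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, 3, 1, 1, rng, bias=False)
        self.bn2 = BatchNorm3d(cout)
        if stride != 1 or cin != cout:
            self.shortcut = Sequential(
                Conv3d(cin, cout, 1, stride, 0, rng, bias=False),
                BatchNorm3d(cout))
        else:
            self.shortcut = None
        self._out_mask = None

    def forward(self, x, train: bool = False):
        main = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(
                    self.bn1.forward(self.conv1.forward(x, train), train), train),
                train), train)
        short = x if self.shortcut is None else self.shortcut.forward(x, train)
        out = main + short
        self._out_mask = out > 0
        return out * self._out_mask

    def backward(self, grad):
        grad = grad * self._out_mask
        dmain = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(
                    self.conv2.backward(self.bn2.backward(grad)))))
        dshort = grad if self.shortcut is None else self.shortcut.backward(grad)
        return dmain + dshort


class SEBlock(Module):
    """Channelwise gating: pool -> dense -> relu -> dense -> sigmoid -> scale."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        mid = max(1, channels // reduction)
        self.channels = channels
        self.fc1 = Dense(channels, mid, rng)
        self.fc2 = Dense(mid, channels, rng)
        self._cache = None

    def forward(self, x, train: bool = False):
        if x.shape[1] != self.channels:
            raise ValueError(
                f"SE block built for {self.channels} channels, got {x.shape[1]}")
        s = x.mean(axis=(2, 3, 4))
        h = self.fc1.forward(s)
        hr = np.maximum(h, 0.0)
        z = self.fc2.forward(hr)
        w = 1.0 / (1.0 + np.exp(-z))
        self._cache = (x, h, w)
        return x * w[:, :, None, None, None]

    def backward(self, grad):
        x, h, w = self._cache
        dx = grad * w[:, :, None, None, None]
        dw = (grad * x).sum(axis=(2, 3, 4))
        dz = dw * w * (1.0 - w)
        dhr = self.fc2.backward(dz)
        dh = dhr * (h > 0)
        ds = self.fc1.backward(dh)
        spatial = x.shape[2] * x.shape[3] * x.shape[4]
        dx = dx + ds[:, :, None, None, None] / spatial
        return dx


class DAFTBlock(Module):
    """Dynamic affine feature-map transform conditioned on tabular data.

    v'_c = alpha_c * v_c + beta_c with (alpha - 1, beta) predicted by a small
    bottleneck MLP on [pooled feature map, tabular vector].
    """

    def __init__(self, channels: int, tab_dim: int, bottleneck_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.tab_dim = tab_dim
        self.fc1 = Dense(channels + tab_dim, bottleneck_dim, rng)
        self.fc2 = Dense(bottleneck_dim, 2 * channels, rng)
        # identity at initialization: alpha = 1 + 0, beta = 0
        self.fc2.W.data[...] = 0.0
        self.fc2.b.data[...] = 0.0
        self._cache = None

    def forward_pair(self, x, tab, train: bool = False):
        if tab.shape[1] != self.tab_dim:
            raise ValueError(
                f"DAFT block expects tabular width {self.tab_dim}, got {tab.shape[1]}")
        s = x.mean(axis=(2, 3, 4))
        z = np.concatenate([s, tab], axis=1)
        h = self.fc1.forward(z)
        hr = np.maximum(h, 0.0)
        ab = self.fc2.forward(hr)
        alpha = 1.0 + ab[:, :self.channels]
        beta = ab[:, self.channels:]
        self._cache = (x, h, alpha)
        return alpha[:, :, None, None, None] * x + beta[:, :, None, None, None]

    def forward(self, x, train: bool = False):  # pragma: no cover - pair API
        raise TypeError("DAFTBlock takes (feature_map, tabular); use forward_pair")

    def backward_pair(self, grad):
        x, h, alpha = self._cache
        c = self.channels
        dalpha = (grad * x).sum(axis=(2, 3, 4))
        dbeta = grad.sum(axis=(2, 3, 4))
        dab = np.concatenate([dalpha, dbeta], axis=1)
        dhr = self.fc2.backward(dab)
        dh = dhr * (h > 0)
        dz = self.fc1.backward(dh)
        ds, dtab = dz[:, :c], dz[:, c:]
        spatial = x.shape[2] * x.shape[3] * x.shape[4]
        dx = grad * alpha[:, :, None, None, None] + ds[:, :, None, None, None] / spatial
        return dx, dtab

    def backward(self, grad):  # pragma: no cover - pair API
        raise TypeError("DAFTBlock takes (feature_map, tabular); use backward_pair")
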