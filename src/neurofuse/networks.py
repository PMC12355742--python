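"""Neural architectures: 3D ResNet-10 (with optional squeeze-and-excite),
convolutional autoencoder, single-layer classifier head, and the DAFT
conditioned-feature-map fusion baseline.

All architectures are declared by small spec dataclasses and built with
``build(spec, seed)``; parameter groups carry addressable names (stem,
stage1..stage4, se, encoder, decoder, classifier) so training regimes can
freeze them selectively.  The classifier is a single dense layer mapping the
concatenated enabled feature blocks to one logit, read literally as a
single-layer network.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import (Adam, BatchNorm3d, Conv3d, ConvTranspose3d, DAFTBlock, Dense,
                 GlobalAvgPool3d, MaxPool3d, Module, ReLU, ResidualBlock,
                 SEBlock, Sequential)


class SpecError(ValueError):
    """Architecture spec infeasible for the given input."""


@dataclass
class ResNetSpec:
    """ResNet-10: 7^3 stem + one basic residual block per stage."""

    in_channels: int = 1
    widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    stage_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    se_enabled: bool = False
    se_reduction: int = 16

    @property
    def feature_width(self) -> int:
        return self.widths[-1]


@dataclass
class AutoencoderSpec:
    """Strided conv encoder -> dense bottleneck -> mirrored transposed-conv
    decoder with a linear output layer."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    channels: tuple[int, ...] = (8, 16, 32)
    latent_dim: int = 64

    def __post_init__(self):
        if self.latent_dim < 1:
            raise SpecError("latent dimension must be positive")
        if any(g < 8 for g in self.grid_shape):
            raise SpecError("autoencoder grid must be at least 8 per axis")


@dataclass
class ClassifierSpec:
    """Single dense layer on concatenated feature blocks -> one logit."""

    block_widths: dict[str, int] = field(default_factory=dict)

    @property
    def input_width(self) -> int:
        return sum(self.block_widths.values())


@dataclass
class DaftSpec:
    """DAFT fusion: per-channel affine modulation of the last residual
    stage's feature map, conditioned on the tabular vector."""

    resnet: ResNetSpec = field(default_factory=ResNetSpec)
    tab_dim: int = 0
    bottleneck_dim: int = 8


def _ceil_half(d: int) -> int:
    return (d + 1) // 2


class ResNetBackbone(Module):
    """Feature extractor; ``forward_map`` exposes the last spatial map."""

    def __init__(self, spec: ResNetSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        w = spec.widths
        self.stem = Sequential(
            Conv3d(spec.in_channels, w[0], 7, 2, 3, rng, bias=False),
            BatchNorm3d(w[0]), ReLU(), MaxPool3d(3, 2, 1))
        self.stem.modules[0]._is_input_layer = True
        self.stage1 = ResidualBlock(w[0], w[0], spec.stage_strides[0], rng)
        self.stage2 = ResidualBlock(w[0], w[1], spec.stage_strides[1], rng)
        self.stage3 = ResidualBlock(w[1], w[2], spec.stage_strides[2], rng)
        self.stage4 = ResidualBlock(w[2], w[3], spec.stage_strides[3], rng)
        self.se = SEBlock(w[3], spec.se_reduction, rng) if spec.se_enabled else None
        self.gap = GlobalAvgPool3d()
        self.activations: dict[str, np.ndarray] = {}
        self.activation_grads: dict[str, np.ndarray] = {}

    _ORDER = ("stem", "stage1", "stage2", "stage3", "stage4")

    def forward_map(self, x, train: bool = False, record: bool = False):
        if any(d < 16 for d in x.shape[2:]):
            raise SpecError("resnet stem needs an input grid of at least 16^3")
        self.activations = {}
        for name in self._ORDER:
            x = getattr(self, name).forward(x, train=train)
            if record:
                self.activations[name] = x
        if self.se is not None:
            x = self.se.forward(x, train=train)
            if record:
                self.activations["se"] = x
        return x

    def forward(self, x, train: bool = False, record: bool = False):
        return self.gap.forward(self.forward_map(x, train, record), train=train)

    def backward(self, dfeat):
        """Backprop from pooled features; stores per-stage output grads."""
        self.activation_grads = {}
        g = self.gap.backward(dfeat)
        if self.se is not None:
            self.activation_grads["se"] = g
            g = self.se.backward(g)
        for name in reversed(self._ORDER):
            self.activation_grads[name] = g
            g = getattr(self, name).backward(g)
        return g


class ResNetClassifier(Module):
    """Backbone features (optionally concatenated with tabular blocks)
    through a single dense layer to one logit."""

    def __init__(self, spec: ResNetSpec, tab_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.backbone = ResNetBackbone(spec, rng)
        self.tab_dim = tab_dim
        self.classifier = Dense(spec.feature_width + tab_dim, 1, rng)

    def forward(self, x, tab=None, train: bool = False, record: bool = False):
        feats = self.backbone.forward(x, train=train, record=record)
        if self.tab_dim:
            if tab is None or tab.shape[1] != self.tab_dim:
                raise SpecError(f"expected tabular width {self.tab_dim}")
            feats = np.concatenate([feats, tab], axis=1)
        self._featw = self.backbone.spec.feature_width
        return self.classifier.forward(feats, train=train)

    def backward(self, dlogit):
        dz = self.classifier.backward(dlogit)
        dfeat, dtab = dz[:, :self._featw], dz[:, self._featw:]
        self.backbone.backward(dfeat)
        return dtab


class DaftClassifier(Module):
    """DAFT baseline: tabular data modulates the last residual stage's
    feature map channelwise; pooled modulated features feed the classifier."""

    def __init__(self, spec: DaftSpec, rng: np.random.Generator):
        super().__init__()
        if spec.tab_dim < 1:
            raise SpecError("DAFT requires a tabular conditioning vector")
        self.spec = spec
        self.backbone = ResNetBackbone(spec.resnet, rng)
        self.daft = DAFTBlock(spec.resnet.feature_width, spec.tab_dim,
                              spec.bottleneck_dim, rng)
        self.gap = GlobalAvgPool3d()
        self.classifier = Dense(spec.resnet.feature_width, 1, rng)

    def forward(self, x, tab=None, train: bool = False, record: bool = False):
        fmap = self.backbone.forward_map(x, train=train, record=record)
        mod = self.daft.forward_pair(fmap, tab, train=train)
        pooled = self.gap.forward(mod, train=train)
        return self.classifier.forward(pooled, train=train)

    def backward(self, dlogit):
        dpooled = self.classifier.backward(dlogit)
        dmod = self.gap.backward(dpooled)
        dmap, dtab = self.daft.backward_pair(dmod)
        g = dmap
        self.backbone.activation_grads = {}
        if self.backbone.se is not None:
            self.backbone.activation_grads["se"] = g
            g = self.backbone.se.backward(g)
        for name in reversed(self.backbone._ORDER):
            self.backbone.activation_grads[name] = g
            g = getattr(self.backbone, name).backward(g)
        return dtab


class Autoencoder(Module):
    """Conv encoder to a dense latent vector, mirrored transposed-conv
    decoder; trained with the masked volume as both input and target."""

    def __init__(self, spec: AutoencoderSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        chans = (1,) + tuple(spec.channels)
        enc = []
        shapes = [tuple(spec.grid_shape)]
        for cin, cout in zip(chans[:-1], chans[1:]):
            enc += [Conv3d(cin, cout, 3, 2, 1, rng, bias=False),
                    BatchNorm3d(cout), ReLU()]
            shapes.append(tuple(_ceil_half(d) for d in shapes[-1]))
        enc[0]._is_input_layer = True
        self.encoder = Sequential(*enc)
        self._shapes = shapes
        self._flat = int(np.prod(shapes[-1])) * chans[-1]
        self.enc_fc = Dense(self._flat, spec.latent_dim, rng)
        self.dec_fc = Dense(spec.latent_dim, self._flat, rng)
        dec = []
        rev = list(reversed(chans))
        for i, (cin, cout) in enumerate(zip(rev[:-1], rev[1:])):
            target = shapes[-(i + 2)]
            source = shapes[-(i + 1)]
            op = tuple(t - (2 * s - 1) for t, s in zip(target, source))
            dec.append(ConvTranspose3d(cin, cout, 3, 2, 1, op, rng))
            if i < len(rev) - 2:  # last layer stays linear
                dec += [BatchNorm3d(cout), ReLU()]
        self.decoder = Sequential(*dec)
        self._bottleneck_shape = (chans[-1],) + shapes[-1]

    def encode(self, x, train: bool = False):
        h = self.encoder.forward(x, train=train)
        self._enc_shape = h.shape
        return self.enc_fc.forward(h.reshape(h.shape[0], -1), train=train)

    def decode(self, z, train: bool = False):
        h = self.dec_fc.forward(z, train=train)
        h = h.reshape((z.shape[0],) + self._bottleneck_shape)
        return self.decoder.forward(h, train=train)

    def forward(self, x, train: bool = False):
        return self.decode(self.encode(x, train=train), train=train)

    def backward(self, drecon):
        dh = self.decoder.backward(drecon)
        dz = self.dec_fc.backward(dh.reshape(dh.shape[0], -1))
        dflat = self.enc_fc.backward(dz)
        return self.encoder.backward(dflat.reshape(self._enc_shape))

    def parameter_groups(self) -> dict[str, list[str]]:
        groups = {"encoder": [], "decoder": []}
        for name, _ in self.named_parameters():
            head = name.split(".")[0]
            groups["encoder" if head in ("encoder", "enc_fc") else "decoder"].append(name)
        return groups

    def freeze_encoder(self, frozen: bool = True):
        self.encoder.freeze(frozen)
        self.enc_fc.freeze(frozen)
        return self


class LinearClassifier(Module):
    """The single-layer classifier head used by every arm."""

    def __init__(self, spec: ClassifierSpec, rng: np.random.Generator):
        super().__init__()
        if spec.input_width < 1:
            raise SpecError("classifier needs at least one input block")
        self.spec = spec
        self.classifier = Dense(spec.input_width, 1, rng)

    def forward(self, x, train: bool = False):
        if x.shape[1] != self.spec.input_width:
            raise SpecError(
                f"expected input width {self.spec.input_width}, got {x.shape[1]}")
        return self.classifier.forward(x, train=train)

    def backward(self, grad):
        return self.classifier.backward(grad)

    def predict_proba(self, x) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.forward(x).ravel()))


def build(spec, seed: int = 0, tab_dim: int = 0) -> Module:
    """Construct a randomly initialized model from its spec, seedably."""
    rng = np.random.default_rng(seed)
    if isinstance(spec, ResNetSpec):
        return ResNetClassifier(spec, tab_dim, rng)
    if isinstance(spec, AutoencoderSpec):
        return Autoencoder(spec, rng)
    if isinstance(spec, ClassifierSpec):
        return LinearClassifier(spec, rng)
    if isinstance(spec, DaftSpec):
        return DaftClassifier(spec, rng)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


def se_forward(feature_map: np.ndarray, se: SEBlock) -> np.ndarray:
    """Squeeze-and-excite recalibration of a (N, C, D, H, W) map."""
    return se.forward(feature_map)


def daft_forward(feature_map: np.ndarray, tabular: np.ndarray,
                 daft: DAFTBlock) -> np.ndarray:
    """DAFT channelwise affine modulation conditioned on tabular data."""
    return daft.forward_pair(feature_map, tabular)


def encode(volumes, model: Autoencoder, batch_size: int = 32) -> np.ndarray:
    """Latent embeddings, one row per volume, deterministic (inference mode)."""
    data = volumes.data if hasattr(volumes, "data") else np.asarray(volumes)
    if data.shape[2:] != tuple(model.spec.grid_shape):
        raise SpecError(f"volume grid {data.shape[2:]} does not match "
                        f"autoencoder grid {tuple(model.spec.grid_shape)}")
    rows = []
    for start in range(0, data.shape[0], batch_size):
        rows.append(model.encode(data[start:start + batch_size], train=False))
    return np.vstack(rows)


def count_parameters(model: Module, groups: list[str] | None = None,
                     trainable_only: bool = False) -> int:
    """Exact parameter count, optionally restricted to named groups.

    A group name matches any dot-separated segment of the parameter path
    (so "stage1" selects backbone.stage1.* wherever the backbone sits).
    """
    named = list(model.named_parameters())
    if groups is not None:
        matched = {g: False for g in groups}
        selected = []
        for name, p in named:
            segs = name.split(".")
            for g in groups:
                if g in segs:
                    matched[g] = True
                    selected.append((name, p))
                    break
        missing = [g for g, ok in matched.items() if not ok]
        if missing:
            raise KeyError(f"unknown parameter group(s): {missing}")
        named = selected
    return sum(p.size for _, p in named
               if not (trainable_only and p.frozen))


def save_checkpoint(model: Module, path: str | Path, meta: dict | None = None):
    """Single-file checkpoint: arrays plus a JSON header."""
    import hashlib

    state = nn.state_arrays(model)
    header = {"format": "neurofuse-ckpt-1",
              "groups": sorted({n.split(".")[0] for n in state}),
              "spec_hash": hashlib.sha256(
                  json.dumps(_spec_dict(model), sort_keys=True).encode()
              ).hexdigest()[:16],
              "meta": meta or {}}
    buf = io.BytesIO()
    np.savez(buf, __header__=np.frombuffer(
        json.dumps(header, sort_keys=True).encode(), dtype=np.uint8), **state)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(model: Module, path: str | Path) -> dict:
    with np.load(str(path)) as npz:
        header = json.loads(bytes(npz["__header__"]))
        state = {k: npz[k] for k in npz.files if k != "__header__"}
    nn.load_state(model, state)
    return header


def _spec_dict(model: Module) -> dict:
    spec = getattr(model, "spec", None)
    try:
        return asdict(spec) if spec is not None else {}
    except TypeError:  # pragma: no cover - non-dataclass spec
        return {}
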