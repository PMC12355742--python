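"""Grad-CAM saliency volumes for the CNN branches.

Channel weights are the spatial means of the logit's gradient with respect
to a chosen stage's activations; the heat map is the rectified weighted sum
of those activations, trilinearly upsampled to the input grid and normalized
to a maximum of 1 when nonzero.  The autoencoder-embedding classifier has no
spatial feature map at the classifier, so it is explicitly unsupported.

``localization_score`` quantifies the qualitative claim that the model's
region of interest overlaps the lesion: the fraction of total heat that
falls inside the lesion mask, to compare against the chance fraction (the
lesion's share of the brain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import Autoencoder, LinearClassifier
from .nn.functional import trilinear_resize


class UnsupportedBranchError(TypeError):
    """Grad-CAM needs a spatial feature map; the embedding classifier has none."""


@dataclass
class SaliencyVolume:
    heat: np.ndarray          # non-negative, input grid, max 1 when nonzero
    target_layer: str
    model_name: str

    def validate(self):
        if (self.heat < 0).any():
            raise ValueError("heat must be non-negative")
        return self


def gradcam(model, volume: np.ndarray, tab: np.ndarray | None = None,
            target_layer: str = "stage4") -> SaliencyVolume:
    """Grad-CAM heat volume for one input.

    ``volume`` is (1, 1, D, H, W) or (D, H, W); ``target_layer`` names a
    backbone stage (stem, stage1..stage4, se).  Runs in inference mode, so
    repeated calls are bit-identical.
    """
    if isinstance(model, (Autoencoder, LinearClassifier)) or \
            not hasattr(model, "backbone"):
        raise UnsupportedBranchError(
            "Grad-CAM requires a CNN branch with spatial feature maps; "
            f"got {type(model).__name__}")
    x = np.asarray(volume, dtype=float)
    if x.ndim == 3:
        x = x[None, None]
    if x.ndim != 5 or x.shape[0] != 1:
        raise ValueError("gradcam takes a single volume")

    logit = model.forward(x, tab=tab, train=False, record=True)
    model.zero_grad()
    model.backward(np.ones_like(logit))
    bb = model.backbone
    if target_layer not in bb.activations:
        raise KeyError(f"unknown target layer {target_layer!r}; "
                       f"have {sorted(bb.activations)}")
    act = bb.activations[target_layer][0]        # (C, d, h, w)
    grad = bb.activation_grads[target_layer][0]
    weights = grad.mean(axis=(1, 2, 3))
    cam = np.maximum((weights[:, None, None, None] * act).sum(axis=0), 0.0)
    heat = trilinear_resize(cam, x.shape[2:])
    heat = np.maximum(heat, 0.0)
    peak = heat.max()
    if peak > 0:
        heat = heat / peak
    return SaliencyVolume(heat=heat, target_layer=target_layer,
                          model_name=type(model).__name__).validate()


def localization_score(saliency: SaliencyVolume | np.ndarray,
                       lesion_mask: np.ndarray) -> float:
    """Fraction of total heat inside the lesion mask (0 when heat is zero)."""
    heat = saliency.heat if isinstance(saliency, SaliencyVolume) else saliency
    if heat.shape != lesion_mask.shape:
        raise ValueError(f"heat {heat.shape} vs lesion mask {lesion_mask.shape}")
    total = float(heat.sum())
    if total == 0.0:
        return 0.0
    return float((heat * lesion_mask).sum()) / total


def chance_fraction(lesion_mask: np.ndarray, brain_mask: np.ndarray) -> float:
    """The lesion's share of the brain: the score a spatially uninformative
    (uniform within brain) heat map would get."""
    return float(lesion_mask.sum()) / float(brain_mask.sum())
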