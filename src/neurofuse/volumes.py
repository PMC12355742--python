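"""Volumetric I/O and image-side preprocessing shared by all image branches.

Brain-mask multiplication happens at load time, so every downstream consumer
sees zeros outside the brain.  Resampling uses trilinear interpolation for
intensities and nearest-neighbour for masks; the lesion-volume image-derived
feature always comes from the native grid, never from a resampled mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .phantom import VolumeSample


class AlignmentError(ValueError):
    """Image and mask grids disagree."""


class MaskError(ValueError):
    """A mask volume carries values other than 0 and 1."""


@dataclass
class VolumeBatch:
    """Stacked single-channel volumes (batch, 1, depth, height, width)."""

    data: np.ndarray
    subject_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 5 or self.data.shape[1] != 1:
            raise ValueError("expected (batch, 1, depth, height, width)")
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("one subject id per volume required")

    def __len__(self) -> int:
        return self.data.shape[0]


def load_volume(image_path: str | Path, brain_mask_path: str | Path,
                lesion_mask_path: str | Path | None = None,
                subject_id: str | None = None) -> VolumeSample:
    """Load a NIfTI volume, apply its brain mask voxelwise, keep provenance."""
    img = nib.load(str(image_path))
    msk = nib.load(str(brain_mask_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    mask = np.asarray(msk.get_fdata())
    if data.shape != mask.shape:
        raise AlignmentError(
            f"image {data.shape} vs brain mask {mask.shape}")
    if np.abs(mask - np.round(mask)).max() > 1e-6 or \
            not np.isin(np.round(mask), (0, 1)).all():
        raise MaskError("brain mask must be binary")
    mask = np.round(mask).astype(np.uint8)
    if lesion_mask_path is not None:
        les = np.asarray(nib.load(str(lesion_mask_path)).get_fdata())
        if les.shape != data.shape:
            raise AlignmentError("lesion mask grid mismatch")
        if np.abs(les - np.round(les)).max() > 1e-6:
            raise MaskError("lesion mask must be binary")
        lesion = np.round(les).astype(np.uint8)
    else:
        lesion = np.zeros_like(mask)
    spacing = img.header.get_zooms()[:3]
    voxel_volume = float(np.prod(spacing))
    sid = subject_id or Path(image_path).name.split("_")[0]
    return VolumeSample(image=data * mask, brain_mask=mask, lesion_mask=lesion,
                        subject_id=sid, voxel_volume=voxel_volume).validate()


def resample_to_grid(vol: VolumeSample, target_shape,
                     max_upsample: float = 8.0) -> VolumeSample:
    """Resample to a model grid: image trilinear, masks nearest-neighbour."""
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 8 for t in target_shape):
        raise ValueError("target grid must be at least 8 voxels per axis")
    src = vol.image.shape
    if any(t / s > max_upsample for t, s in zip(target_shape, src)):
        raise ValueError(f"upsampling beyond {max_upsample}x per axis refused")
    if target_shape == src:
        return vol
    factors = [t / s for t, s in zip(target_shape, src)]
    image = ndimage.zoom(vol.image, factors, order=1, grid_mode=True,
                         mode="nearest")
    brain = ndimage.zoom(vol.brain_mask, factors, order=0, grid_mode=True,
                         mode="nearest")
    lesion = ndimage.zoom(vol.lesion_mask, factors, order=0, grid_mode=True,
                          mode="nearest")
    scale = np.prod(src) / np.prod(target_shape)
    return VolumeSample(image=image * brain, brain_mask=brain.astype(np.uint8),
                        lesion_mask=(lesion.astype(np.uint8)
                                     & brain.astype(np.uint8)),
                        subject_id=vol.subject_id,
                        voxel_volume=vol.voxel_volume * scale).validate()


def stack_volumes(vols: list[VolumeSample], target_shape=None,
                  zscore: bool = False) -> VolumeBatch:
    """Mask-applied volumes stacked for the networks, optionally resampled.

    ``zscore`` standardizes within the brain mask per volume; off by default
    because published inputs are already intensity normalized.
    """
    out = []
    ids = []
    for v in vols:
        if target_shape is not None and tuple(target_shape) != v.image.shape:
            v = resample_to_grid(v, target_shape)
        img = v.image * v.brain_mask
        if zscore:
            inside = v.brain_mask.astype(bool)
            mu, sd = img[inside].mean(), img[inside].std()
            img = np.where(inside, (img - mu) / (sd if sd > 0 else 1.0), 0.0)
        out.append(img[None])
        ids.append(v.subject_id)
    return VolumeBatch(data=np.stack(out), subject_ids=ids,
                       provenance={"n": len(ids),
                                   "zscore": zscore,
                                   "grid": list(out[0].shape[1:])})
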