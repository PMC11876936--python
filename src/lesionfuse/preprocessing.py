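"""Standardization of heterogeneous volumes to the network's input tensor.

The canonical pipeline mirrors a common clinical-MRI preparation:

1. zero-pad every volume, centered, to a fixed canonical grid of
   (32, 256, 256) — chosen larger than any input, so no cropping is
   ever performed;
2. rescale intensities per study onto [0, 1] by the min–max map;
3. block-average the in-plane axes 4x down to the (32, 64, 64) grid the
   two-branch network consumes, with the lesion mask following by
   majority vote (ties count as foreground).

Padding offsets are recorded so the canonical transform is invertible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CANONICAL_SHAPE = (32, 256, 256)
MODEL_INPUT_SHAPE = (32, 64, 64)


class DimensionError(ValueError):
    """Input exceeds the canonical grid (no cropping is defined)."""


@dataclass
class CanonicalVolume:
    """Channel-first volume on the canonical grid plus provenance."""

    data: np.ndarray  # (C, 32, 256, 256)
    provenance: dict = field(default_factory=dict)


@dataclass
class ModelInput:
    """Network-ready tensor (C, 32, 64, 64) with an aligned low-res mask."""

    data: np.ndarray
    mask_lowres: np.ndarray


def pad_to_canonical(volume: np.ndarray,
                     canonical_shape: tuple[int, int, int] = CANONICAL_SHAPE) -> CanonicalVolume:
    """Center ``volume`` in a zero canonical grid; intensity sum preserved."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim == 3:
        volume = volume[None]
    if volume.ndim != 4:
        raise ValueError(f"expected 3-D or 4-D input, got ndim={volume.ndim}")
    spatial = volume.shape[1:]
    if any(s > c for s, c in zip(spatial, canonical_shape)):
        raise DimensionError(
            f"spatial shape {spatial} exceeds canonical {canonical_shape}")
    offsets = tuple((c - s) // 2 for s, c in zip(spatial, canonical_shape))
    out = np.zeros((volume.shape[0],) + tuple(canonical_shape), dtype=volume.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offsets, spatial))
    out[(slice(None),) + sl] = volume
    return CanonicalVolume(
        data=out,
        provenance={"original_shape": spatial, "offsets": offsets,
                    "canonical_shape": tuple(canonical_shape)},
    )


def unpad(cv: CanonicalVolume) -> np.ndarray:
    """Invert :func:`pad_to_canonical` using recorded provenance."""
    offsets = cv.provenance["offsets"]
    spatial = cv.provenance["original_shape"]
    sl = tuple(slice(o, o + s) for o, s in zip(offsets, spatial))
    return cv.data[(slice(None),) + sl]


def rescale_intensity(volume: np.ndarray) -> np.ndarray:
    """Per-study min–max rescaling onto [0, 1]; monotone in the voxel order.

    A constant volume maps to all zeros (with a warning): there is no
    scale information to preserve.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite intensities")
    vmin, vmax = volume.min(), volume.max()
    if vmax == vmin:
        warnings.warn("constant volume: rescale_intensity returns all zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(volume)
    return (volume - vmin) / (vmax - vmin)


def _block_mean_inplane(data: np.ndarray, f: int) -> np.ndarray:
    """Average f x f in-plane blocks of a (..., H, W) array."""
    *lead, H, W = data.shape
    v = data.reshape(*lead, H // f, f, W // f, f)
    return v.mean(axis=(-3, -1))


def resample_to_model_input(cv: CanonicalVolume, mask: np.ndarray,
                            factor: int = 4) -> ModelInput:
    """4x in-plane downsampling: block mean for intensities, majority
    vote for the mask (ties -> foreground). The slice axis is untouched.
    """
    data = cv.data
    if data.shape[1:] != tuple(cv.provenance.get("canonical_shape", data.shape[1:])):
        raise ValueError("canonical volume shape inconsistent with provenance")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != data.shape[1:]:
        raise ValueError("mask must match canonical spatial shape")
    low = _block_mean_inplane(data, factor)
    frac = _block_mean_inplane(mask.astype(np.float64), factor)
    mask_low = frac >= 0.5  # majority vote; exact half counts as foreground
    return ModelInput(data=low, mask_lowres=mask_low)


def prepare_study(volume: np.ndarray, mask: np.ndarray,
                  model_shape: tuple[int, int, int] = MODEL_INPUT_SHAPE) -> ModelInput:
    """Full path from a raw study to a network input.

    Volumes already on the model grid are only intensity-rescaled (the
    phantom generator emits them at network resolution); anything else
    goes through the canonical pad/rescale/downsample chain, which
    requires the model grid to be the canonical in-plane 4x reduction.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim == 3:
        volume = volume[None]
    if volume.shape[1:] == tuple(model_shape):
        return ModelInput(data=rescale_intensity(volume),
                          mask_lowres=np.asarray(mask).astype(bool))
    # rescale before padding so padded voxels stay exactly zero in [0,1]
    cv = pad_to_canonical(rescale_intensity(volume))
    mask_c = pad_to_canonical(np.asarray(mask, dtype=np.float64)).data[0] > 0.5
    mi = resample_to_model_input(cv, mask_c)
    if mi.data.shape[1:] != tuple(model_shape):
        raise DimensionError(
            f"canonical path yields {mi.data.shape[1:]}, expected {model_shape}")
    return mi
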