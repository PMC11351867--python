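"""Loading, resampling and normalisation of co-registered multi-channel slices.

A patient is stored as three co-registered single-modality volumes (T2W-like,
ADC-like, high-b-value-DWI-like) plus a binary label volume, all NIfTI. The
loader resamples the functional channels and the label onto the reference
(first-channel) grid, then yields per-slice records.

Normalisation: each channel is min-max scaled to [0,1] over the patient
volume and then standardised to zero mean / unit variance over the volume.
Degenerate (constant) channels become all-zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import LoadError

__all__ = [
    "MultiModalSlice", "BinaryMask", "ChannelStats",
    "load_patient", "resample_slice", "resample_mask", "normalize_channels",
    "volume_channel_stats",
]

CHANNEL_NAMES = ("t2w", "adc", "dwi_hb")


@dataclass
class MultiModalSlice:
    """One H×W×3 co-registered image slice."""

    pixels: np.ndarray                 # (H, W, 3) float32
    spacing_mm: tuple[float, float]    # (row, col)
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("non-finite pixel values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """Binary lesion mask aligned with its slice."""

    pixels: np.ndarray                 # (H, W) bool
    spacing_mm: tuple[float, float]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected (H, W) mask, got {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ChannelStats:
    """Per-volume per-channel normalisation constants."""

    minimum: np.ndarray   # (3,)
    maximum: np.ndarray   # (3,)
    mean_scaled: np.ndarray
    sd_scaled: np.ndarray


def _load_volume(path: str) -> tuple[np.ndarray, np.ndarray]:
    if not os.path.exists(path):
        raise LoadError(f"volume not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise LoadError(f"expected a 3D volume in {path}, got shape {data.shape}")
    return data, img.affine


def _resample_to(data: np.ndarray, target_shape: tuple[int, ...], order: int) -> np.ndarray:
    if data.shape == tuple(target_shape):
        return data
    factors = [t / s for t, s in zip(target_shape, data.shape)]
    out = ndimage.zoom(data, factors, order=order, mode="nearest", grid_mode=True)
    if out.shape != tuple(target_shape):  # guard against zoom rounding
        raise LoadError(f"resampling produced {out.shape}, wanted {target_shape}")
    return out


def load_patient(t2w_path: str, adc_path: str, dwi_path: str, label_path: str,
                 patient_id: str | None = None,
                 normalize: bool = False) -> list[tuple[MultiModalSlice, BinaryMask]]:
    """Load one patient and return (slice, mask) pairs in ascending slice order.

    The first channel defines the reference grid; the other channels are
    resampled linearly onto it and the label with nearest-neighbour. Volumes
    are stored (H, W, S) with in-plane spacing in the affine diagonal.
    """
    ref, affine = _load_volume(t2w_path)
    channels = [ref]
    for path in (adc_path, dwi_path):
        vol, _ = _load_volume(path)
        if vol.shape[2] != ref.shape[2] and vol.shape != ref.shape:
            raise LoadError(f"slice count mismatch after resampling: {path}")
        channels.append(_resample_to(vol, ref.shape, order=1))
    label, _ = _load_volume(label_path)
    label = _resample_to(label, ref.shape, order=0) > 0.5
    spacing = (float(abs(affine[0, 0])) or 1.0, float(abs(affine[1, 1])) or 1.0)
    if patient_id is None:
        patient_id = os.path.basename(t2w_path).split("_")[0]

    stack = np.stack(channels, axis=-1)  # (H, W, S, 3)
    stats = volume_channel_stats(stack) if normalize else None
    out = []
    for s in range(ref.shape[2]):
        sl = MultiModalSlice(pixels=stack[:, :, s, :], spacing_mm=spacing,
                             patient_id=patient_id, slice_index=s)
        if stats is not None:
            sl = normalize_channels(sl, stats)
        out.append((sl, BinaryMask(pixels=label[:, :, s], spacing_mm=spacing)))
    return out


def volume_channel_stats(stack: np.ndarray) -> ChannelStats:
    """Normalisation constants over a whole (.., 3) volume stack."""
    flat = stack.reshape(-1, 3).astype(np.float64)
    mn, mx = flat.min(axis=0), flat.max(axis=0)
    rng = np.where(mx > mn, mx - mn, 1.0)
    scaled = (flat - mn) / rng
    sd = scaled.std(axis=0)
    return ChannelStats(minimum=mn, maximum=mx,
                        mean_scaled=scaled.mean(axis=0),
                        sd_scaled=np.where(sd > 0, sd, 1.0))


def normalize_channels(sl: MultiModalSlice,
                       stats: ChannelStats | None = None) -> MultiModalSlice:
    """Min-max scale each channel to [0,1], then z-score it.

    When ``stats`` is given the constants come from the patient volume
    (the intended use); otherwise they are computed from this slice alone.
    Constant channels map to all zeros.
    """
    px = sl.pixels.astype(np.float64)
    if stats is None:
        stats = volume_channel_stats(px[:, :, None, :].reshape(*px.shape[:2], 1, 3))
    out = np.zeros_like(px)
    for c in range(3):
        mn, mx = stats.minimum[c], stats.maximum[c]
        if mx <= mn:
            continue
        scaled = (px[:, :, c] - mn) / (mx - mn)
        out[:, :, c] = (scaled - stats.mean_scaled[c]) / stats.sd_scaled[c]
    return MultiModalSlice(pixels=out.astype(np.float32), spacing_mm=sl.spacing_mm,
                           patient_id=sl.patient_id, slice_index=sl.slice_index)


def normalize_patient(pairs: list[tuple[MultiModalSlice, BinaryMask]]
                      ) -> list[tuple[MultiModalSlice, BinaryMask]]:
    """Normalise all slices of one patient with shared per-volume stats."""
    stack = np.stack([sl.pixels for sl, _ in pairs], axis=2)  # (H, W, S, 3)
    stats = volume_channel_stats(stack)
    return [(normalize_channels(sl, stats), m) for sl, m in pairs]


def resample_slice(sl: MultiModalSlice, target_size: int = 256) -> MultiModalSlice:
    """Resample to ``target_size`` square with linear interpolation."""
    if target_size < 32:
        raise ValueError("target_size must be >= 32")
    h, w = sl.shape
    if (h, w) == (target_size, target_size):
        return sl
    out = ndimage.zoom(sl.pixels, (target_size / h, target_size / w, 1.0),
                       order=1, mode="nearest", grid_mode=True)
    spacing = (sl.spacing_mm[0] * h / target_size,
               sl.spacing_mm[1] * w / target_size)
    return MultiModalSlice(pixels=out.astype(np.float32), spacing_mm=spacing,
                           patient_id=sl.patient_id, slice_index=sl.slice_index)


def resample_mask(mask: BinaryMask, target_size: int = 256) -> BinaryMask:
    """Nearest-neighbour mask resampling matching :func:`resample_slice`."""
    if target_size < 32:
        raise ValueError("target_size must be >= 32")
    h, w = mask.shape
    if (h, w) == (target_size, target_size):
        return mask
    out = ndimage.zoom(mask.pixels.astype(np.uint8),
                       (target_size / h, target_size / w),
                       order=0, mode="nearest", grid_mode=True) > 0
    spacing = (mask.spacing_mm[0] * h / target_size,
               mask.spacing_mm[1] * w / target_size)
    return BinaryMask(pixels=out, spacing_mm=spacing)
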