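"""Shared training plumbing: batching, augmentation, config."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocessing_io import BinaryMask, MultiModalSlice

__all__ = ["TrainConfig", "slices_to_array", "masks_to_array", "augment_batch"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser/schedule settings shared by the three training stages.

    Full-scale defaults mirror the reference regime (Adam, batch 16,
    initial lr 1e-3, polynomial decay with power 0.9); the desk-scale
    profiles used in tests shrink epochs and batch only.
    """

    epochs: int = 200
    batch_size: int = 16
    lr: float = 1e-3
    backbone_lr: float = 1e-4       # rejection backbone only
    weight_decay: float = 0.0
    poly_power: float = 0.9
    augment: bool = True
    seed: int = 0


def slices_to_array(slices: list[MultiModalSlice]) -> np.ndarray:
    """Stack (H, W, 3) slices into a (N, 3, H, W) batch."""
    return np.stack([s.pixels.transpose(2, 0, 1) for s in slices]).astype(np.float32)


def masks_to_array(masks: list[BinaryMask]) -> np.ndarray:
    return np.stack([m.pixels for m in masks]).astype(np.float32)


def augment_batch(x: np.ndarray, y: np.ndarray,
                  rng: np.random.Generator,
                  crop_prob: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Random horizontal flip, quarter-turn rotation, and crop-resize.

    x: (N, C, H, W); y: (N, H, W). The crop keeps 80-100% of the field of
    view and rescales back (linear for images, nearest for masks).
    """
    x = x.copy()
    y = y.copy()
    n, _, h, w = x.shape
    for i in range(n):
        if rng.random() < 0.5:
            x[i] = x[i, :, :, ::-1]
            y[i] = y[i, :, ::-1]
        k = int(rng.integers(0, 4))
        if k:
            x[i] = np.rot90(x[i], k, axes=(1, 2))
            y[i] = np.rot90(y[i], k, axes=(0, 1))
        if rng.random() < crop_prob:
            f = float(rng.uniform(0.8, 1.0))
            ch, cw = max(int(h * f), 8), max(int(w * f), 8)
            r0 = int(rng.integers(0, h - ch + 1))
            c0 = int(rng.integers(0, w - cw + 1))
            img = x[i, :, r0:r0 + ch, c0:c0 + cw]
            msk = y[i, r0:r0 + ch, c0:c0 + cw]
            x[i] = ndimage.zoom(img, (1.0, h / ch, w / cw), order=1,
                                mode="nearest", grid_mode=True)
            y[i] = ndimage.zoom(msk, (h / ch, w / cw), order=0,
                                mode="nearest", grid_mode=True)
    return x, y
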