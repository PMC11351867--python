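"""Bounding-box geometry for prompt provisioning.

Coordinate convention (used package-wide): images are indexed row-major with
0-based pixel indices; ``x`` is the column axis, ``y`` the row axis; boxes are
half-open, covering columns ``[x0, x1)`` and rows ``[y0, y1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BoundingBox", "tight_bbox", "expand_bbox", "simulate_manual_box",
    "augment_box_for_training", "render_box_mask",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity for 2D components


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open box: columns [x0, x1), rows [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {self!r}")
        if min(self.x0, self.y0) < 0:
            raise ValueError(f"negative corner in {self!r}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def contains(self, other: "BoundingBox") -> bool:
        return (self.x0 <= other.x0 and self.y0 <= other.y0
                and self.x1 >= other.x1 and self.y1 >= other.y1)


def tight_bbox(mask: np.ndarray) -> BoundingBox | None:
    """Minimal box containing every true pixel; ``None`` for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(mask.any(axis=0))
    return BoundingBox(x0=int(cols[0]), y0=int(rows[0]),
                       x1=int(cols[-1]) + 1, y1=int(rows[-1]) + 1)


def expand_bbox(box: BoundingBox, ratio: float, width: int, height: int) -> BoundingBox:
    """Grow each dimension by ``ratio`` total (ratio/2 per side).

    Low edges are floored, high edges ceiled (never crops boundary pixels),
    then clipped to the image extent.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    dx = box.width * ratio / 2.0
    dy = box.height * ratio / 2.0
    return BoundingBox(
        x0=max(0, math.floor(box.x0 - dx)),
        y0=max(0, math.floor(box.y0 - dy)),
        x1=min(width, math.ceil(box.x1 + dx)),
        y1=min(height, math.ceil(box.y1 + dy)),
    )


def component_boxes(mask: np.ndarray) -> list[BoundingBox]:
    """One tight box per 8-connected component, in label order."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    out = []
    for sl in ndimage.find_objects(labels):
        if sl is None:  # pragma: no cover - find_objects never yields None here
            continue
        rs, cs = sl
        out.append(BoundingBox(x0=cs.start, y0=rs.start, x1=cs.stop, y1=rs.stop))
    return out


def simulate_manual_box(gt: np.ndarray, ratio: float = 0.4,
                        width: int | None = None,
                        height: int | None = None) -> list[BoundingBox]:
    """Simulated user input: expanded tight box per ground-truth lesion.

    Emulates a reader drawing a generous box around each lesion; one box per
    8-connected component, each grown by ``ratio`` (default 40%).
    """
    gt = np.asarray(gt, dtype=bool)
    h, w = gt.shape
    width = w if width is None else width
    height = h if height is None else height
    return [expand_bbox(b, ratio, width, height) for b in component_boxes(gt)]


def augment_box_for_training(box: BoundingBox, rng: np.random.Generator,
                             width: int, height: int,
                             max_ratio: float = 0.6,
                             max_shift: int = 20) -> BoundingBox:
    """Training-time prompt jitter: random expansion then corner perturbation.

    The expansion ratio is uniform in [0, max_ratio]; each corner coordinate
    is then shifted by an integer uniform in [-max_shift, max_shift], clipped,
    and repaired to a minimum 2x2 extent.
    """
    ratio = float(rng.uniform(0.0, max_ratio))
    b = expand_bbox(box, ratio, width, height)
    shifts = rng.integers(-max_shift, max_shift + 1, size=4)
    x0 = int(np.clip(b.x0 + shifts[0], 0, width - 2))
    y0 = int(np.clip(b.y0 + shifts[1], 0, height - 2))
    x1 = int(np.clip(b.x1 + shifts[2], x0 + 2, width))
    y1 = int(np.clip(b.y1 + shifts[3], y0 + 2, height))
    return BoundingBox(x0=x0, y0=y0, x1=x1, y1=y1)


def render_box_mask(box: BoundingBox, height: int, width: int) -> np.ndarray:
    """Binary image of the box interior (the prompt channel)."""
    m = np.zeros((height, width), dtype=bool)
    m[box.y0:box.y1, box.x0:box.x1] = True
    return m
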