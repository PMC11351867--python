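"""Evaluation metrics: Dice, 95th-percentile Hausdorff distance, lesion-level
detection scores, regression R-squared, rejection ratio, paired tests.

Slice-level metrics compare 2D binary masks. Lesion-level scores treat each
lesion as a 3D entity: connected components are extracted with 26-neighbour
connectivity from stacked per-patient volumes, and a component counts as
detected when its summed overlap fraction with the other segmentation reaches
the threshold tau (default 0.1 — deliberately low, reflecting the large
inter-observer variability in lesion delineation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

__all__ = [
    "LesionMatchConfig", "LesionScores", "EvalReport",
    "dice_coefficient", "hd95", "boundary_pixels", "lesion_level_scores",
    "f1", "r_squared", "rejection_ratio", "paired_t_test",
]

HD_UNDEFINED = float("nan")
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LesionMatchConfig:
    """Matching rule for 3D lesion components."""

    tau: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")


@dataclass(frozen=True)
class LesionScores:
    """Pooled lesion-detection counts plus derived rates.

    ``tpr``/``ppv`` are NaN when the corresponding denominator is empty
    (no ground-truth / no predicted components anywhere).
    """

    tp_gt: int
    n_gt: int
    tp_pred: int
    n_pred: int

    @property
    def tpr(self) -> float:
        return self.tp_gt / self.n_gt if self.n_gt else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp_pred / self.n_pred if self.n_pred else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.ppv, self.tpr
        if np.isnan(p) or np.isnan(r):
            return float("nan")
        return f1(p, r)

    def __add__(self, other: "LesionScores") -> "LesionScores":
        return LesionScores(self.tp_gt + other.tp_gt, self.n_gt + other.n_gt,
                            self.tp_pred + other.tp_pred, self.n_pred + other.n_pred)


def dice_coefficient(pred: np.ndarray, gt: np.ndarray) -> float:
    """DSC = 2|P∩G| / (|P|+|G|); 1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    denom = int(pred.sum()) + int(gt.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(pred, gt).sum()) / denom


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one 4-neighbour outside the mask.

    Pixels on the image border count as boundary (the outside of the image
    is outside the mask).
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1),
                                    border_value=0)
    return mask & ~eroded


def hd95(pred: np.ndarray, gt: np.ndarray,
         spacing_mm: tuple[float, float] = (1.0, 1.0)) -> float:
    """95th-percentile symmetric Hausdorff distance in millimetres.

    Boundary pixels of both masks are mapped to physical coordinates; the
    two directed nearest-neighbour distance sets are pooled and the 95th
    percentile (linear interpolation) of the union is returned. Undefined
    (NaN) when either mask is empty.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    if not pred.any() or not gt.any():
        return HD_UNDEFINED
    sp = np.asarray(spacing_mm, dtype=float)
    bp = np.argwhere(boundary_pixels(pred)) * sp
    bg = np.argwhere(boundary_pixels(gt)) * sp
    d_pg, _ = cKDTree(bg).query(bp, k=1)
    d_gp, _ = cKDTree(bp).query(bg, k=1)
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


def lesion_level_scores(gt_volume: np.ndarray, pred_volume: np.ndarray,
                        cfg: LesionMatchConfig = LesionMatchConfig()) -> LesionScores:
    """Lesion-detection counts on one aligned 3D volume pair.

    A ground-truth component G_i is a true positive when
    sum_j |G_i ∩ P_j| / |G_i| >= tau; since predicted components are
    disjoint this equals |G_i ∩ P| / |G_i|. Predicted components are scored
    symmetrically for precision.
    """
    gt_volume = np.asarray(gt_volume, dtype=bool)
    pred_volume = np.asarray(pred_volume, dtype=bool)
    if gt_volume.shape != pred_volume.shape:
        raise ValueError("misaligned volumes")
    if gt_volume.ndim != 3:
        raise ValueError("expected 3D stacks")

    def _tp_count(components_of: np.ndarray, other: np.ndarray) -> tuple[int, int]:
        labels, n = ndimage.label(components_of, structure=_STRUCT26)
        if n == 0:
            return 0, 0
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        overlaps = ndimage.sum_labels(other.astype(np.float64), labels,
                                      index=range(1, n + 1))
        return int(np.count_nonzero(overlaps / sizes >= cfg.tau)), int(n)

    tp_gt, n_gt = _tp_count(gt_volume, pred_volume)
    tp_pred, n_pred = _tp_count(pred_volume, gt_volume)
    return LesionScores(tp_gt=tp_gt, n_gt=n_gt, tp_pred=tp_pred, n_pred=n_pred)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def r_squared(predicted, target) -> float:
    """Coefficient of determination of predicted quality scores.

    R^2 = 1 - sum (d_i - s_i)^2 / sum (d_i - mean d)^2. Undefined (raises)
    when the targets have zero variance.
    """
    s = np.asarray(predicted, dtype=float)
    d = np.asarray(target, dtype=float)
    if s.shape != d.shape or s.ndim != 1:
        raise ValueError("predicted and target must be equal-length 1D")
    if s.size < 2:
        raise ValueError("need at least two pairs")
    tss = float(np.sum((d - d.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("targets have zero variance; R^2 undefined")
    return 1.0 - float(np.sum((d - s) ** 2)) / tss


def rejection_ratio(scores, t: float) -> float:
    """Fraction of images whose score falls strictly below the threshold."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score list")
    return float(np.count_nonzero(s < t)) / s.size


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on per-image metric lists.

    Identical lists return (0.0, 1.0); nonzero mean difference with zero
    variance is degenerate and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired lists must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if np.all(diff == diff[0]):
        if diff[0] == 0.0:
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences; t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvalReport:
    """Per-image and lesion-level aggregates for one cohort run."""

    t: float
    per_image_dsc: list[float] = field(default_factory=list)
    per_image_hd95: list[float] = field(default_factory=list)
    hd95_excluded: int = 0
    lesion: LesionScores = field(default_factory=lambda: LesionScores(0, 0, 0, 0))
    r2: float = float("nan")
    rejection_ratio: float = float("nan")

    @property
    def dsc_mean(self) -> float:
        return float(np.mean(self.per_image_dsc)) if self.per_image_dsc else float("nan")

    @property
    def dsc_sd(self) -> float:
        return float(np.std(self.per_image_dsc)) if self.per_image_dsc else float("nan")

    @property
    def hd95_mean(self) -> float:
        vals = [v for v in self.per_image_hd95 if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def hd95_sd(self) -> float:
        vals = [v for v in self.per_image_hd95 if not np.isnan(v)]
        return float(np.std(vals)) if vals else float("nan")

    def as_dict(self) -> dict:
        return {
            "t": self.t,
            "dsc_mean": self.dsc_mean, "dsc_sd": self.dsc_sd,
            "hd95_mean": self.hd95_mean, "hd95_sd": self.hd95_sd,
            "hd95_excluded": self.hd95_excluded,
            "lesion_tpr": self.lesion.tpr, "lesion_ppv": self.lesion.ppv,
            "lesion_f1": self.lesion.f1,
            "r2": self.r2, "rejection_ratio": self.rejection_ratio,
        }
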