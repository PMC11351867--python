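"""Cascade orchestration: coarse prediction -> quality score -> gate ->
box provisioning -> prompt-conditioned fine segmentation -> final mask.

Each slice runs through the coarse network; the rejection network scores the
result; the gate routes the slice either to simulated/real manual boxes
(score < t) or to boxes derived from the coarse segmentation's connected
components (score >= t). All boxes are expanded (default 40%) and fed to the
prompt segmenter; per-box fine masks are unioned. Every result carries full
provenance (score, decision, boxes with their source) so a run can be
re-executed exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxes import BoundingBox, component_boxes, expand_bbox, simulate_manual_box
from .coarse_seg import CoarseUNet, predict_batch
from .errors import InteractionRequiredError
from .metrics_eval import (EvalReport, LesionMatchConfig, LesionScores,
                           dice_coefficient, hd95, lesion_level_scores,
                           r_squared, rejection_ratio)
from .prompt_seg import PromptSegmenter
from .rejection import (GateConfig, RejectionNet, RouteDecision, gate,
                        predict_scores, quality_target)
from .synthetic_data import PhantomPatient, SLICE_THICKNESS_MM

__all__ = [
    "CascadeResult", "run_cascade", "run_cohort", "sweep_thresholds",
    "simulated_manual_provider", "results_to_frame", "report_to_json",
]


@dataclass
class CascadeResult:
    patient_id: str
    slice_index: int
    coarse_mask: np.ndarray
    score: float
    decision: RouteDecision
    boxes: list[tuple[str, BoundingBox]] = field(default_factory=list)
    final_mask: np.ndarray | None = None
    target_dice: float | None = None


def simulated_manual_provider(gt_mask: np.ndarray, ratio: float = 0.4):
    """Manual interaction stand-in: expanded ground-truth component boxes."""
    def provider(sl) -> list[BoundingBox]:
        h, w = gt_mask.shape
        return simulate_manual_box(gt_mask, ratio=ratio, width=w, height=h)
    return provider


def _fine_union(segmenter: PromptSegmenter, sl, boxes: list[BoundingBox]) -> np.ndarray:
    h, w = sl.shape
    union = np.zeros((h, w), dtype=bool)
    for b in boxes:
        union |= segmenter.segment(sl, b).binarize()
    return union


def _route_and_segment(sl, coarse_mask: np.ndarray, score: float,
                       segmenter: PromptSegmenter, gate_cfg: GateConfig,
                       manual_box_provider, expansion_ratio: float,
                       gt_mask: np.ndarray | None) -> CascadeResult:
    h, w = sl.shape
    decision = gate(score, gate_cfg)
    if decision is RouteDecision.MANUAL:
        if manual_box_provider is None:
            raise InteractionRequiredError(
                f"slice {sl.patient_id}/{sl.slice_index}: interaction required "
                "but no manual box provider was given")
        boxes = [("MANUAL", b) for b in manual_box_provider(sl)]
    else:
        boxes = [("AUTO", expand_bbox(b, expansion_ratio, w, h))
                 for b in component_boxes(coarse_mask)]
    final = _fine_union(segmenter, sl, [b for _, b in boxes]) if boxes else \
        np.zeros((h, w), dtype=bool)
    target = None if gt_mask is None else quality_target(coarse_mask, gt_mask)
    return CascadeResult(patient_id=sl.patient_id, slice_index=sl.slice_index,
                         coarse_mask=coarse_mask, score=float(score),
                         decision=decision, boxes=boxes, final_mask=final,
                         target_dice=target)


def run_cascade(sl, coarse: CoarseUNet, rejection: RejectionNet,
                segmenter: PromptSegmenter, gate_cfg: GateConfig,
                manual_box_provider=None, expansion_ratio: float = 0.4,
                gt_mask: np.ndarray | None = None) -> CascadeResult:
    """Run one slice through the full cascade."""
    (probs, _), = predict_batch(coarse, [sl], batch_size=1)
    score = float(predict_scores(rejection, coarse, [sl], batch_size=1)[0])
    return _route_and_segment(sl, probs.binarize(), score, segmenter, gate_cfg,
                              manual_box_provider, expansion_ratio, gt_mask)


class _CohortCache:
    """One coarse/rejection pass plus lazily-shared AUTO/MANUAL fine masks."""

    def __init__(self, patients: list[PhantomPatient], coarse: CoarseUNet,
                 rejection: RejectionNet, segmenter: PromptSegmenter,
                 manual_ratio: float, expansion_ratio: float,
                 batch_size: int = 16):
        self.patients = patients
        self.segmenter = segmenter
        self.expansion_ratio = expansion_ratio
        self.manual_ratio = manual_ratio
        self.pairs = [pair for p in patients for pair in p.slices]
        slices = [s for s, _ in self.pairs]
        self.scores = predict_scores(rejection, coarse, slices, batch_size)
        preds = predict_batch(coarse, slices, batch_size)
        self.coarse_masks = [p.binarize() for p, _ in preds]
        self.targets = np.array([
            quality_target(cm, m.pixels)
            for cm, (_, m) in zip(self.coarse_masks, self.pairs)])
        self._auto: dict[int, np.ndarray] = {}
        self._manual: dict[int, np.ndarray] = {}

    def auto_final(self, i: int) -> np.ndarray:
        if i not in self._auto:
            sl, _ = self.pairs[i]
            h, w = sl.shape
            boxes = [expand_bbox(b, self.expansion_ratio, w, h)
                     for b in component_boxes(self.coarse_masks[i])]
            self._auto[i] = (_fine_union(self.segmenter, sl, boxes)
                             if boxes else np.zeros((h, w), dtype=bool))
        return self._auto[i]

    def manual_final(self, i: int) -> np.ndarray:
        if i not in self._manual:
            sl, m = self.pairs[i]
            boxes = simulate_manual_box(m.pixels, ratio=self.manual_ratio)
            h, w = sl.shape
            self._manual[i] = (_fine_union(self.segmenter, sl, boxes)
                               if boxes else np.zeros((h, w), dtype=bool))
        return self._manual[i]

    def results_at(self, t: float) -> list[CascadeResult]:
        gcfg = GateConfig(threshold=t)
        out = []
        for i, (sl, m) in enumerate(self.pairs):
            decision = gate(float(self.scores[i]), gcfg)
            if decision is RouteDecision.MANUAL:
                final = self.manual_final(i)
                boxes = [("MANUAL", b) for b in
                         simulate_manual_box(m.pixels, ratio=self.manual_ratio)]
            else:
                final = self.auto_final(i)
                h, w = sl.shape
                boxes = [("AUTO", expand_bbox(b, self.expansion_ratio, w, h))
                         for b in component_boxes(self.coarse_masks[i])]
            out.append(CascadeResult(
                patient_id=sl.patient_id, slice_index=sl.slice_index,
                coarse_mask=self.coarse_masks[i], score=float(self.scores[i]),
                decision=decision, boxes=boxes, final_mask=final,
                target_dice=float(self.targets[i])))
        return out

    def report_at(self, t: float,
                  match_cfg: LesionMatchConfig = LesionMatchConfig()) -> EvalReport:
        results = self.results_at(t)
        report = EvalReport(t=t)
        for res, (sl, m) in zip(results, self.pairs):
            report.per_image_dsc.append(dice_coefficient(res.final_mask, m.pixels))
            d = hd95(res.final_mask, m.pixels, spacing_mm=m.spacing_mm)
            if np.isnan(d):
                report.hd95_excluded += 1
            report.per_image_hd95.append(d)
        # lesion-level scores pool 26-connected 3D components per patient
        lesion = LesionScores(0, 0, 0, 0)
        offset = 0
        for p in self.patients:
            k = len(p.slices)
            gt_vol = p.gt_volume()
            pred_vol = np.stack([results[offset + j].final_mask for j in range(k)])
            lesion = lesion + lesion_level_scores(gt_vol, pred_vol, match_cfg)
            offset += k
        report.lesion = lesion
        try:
            report.r2 = r_squared(self.scores, self.targets)
        except ValueError:
            report.r2 = float("nan")
        report.rejection_ratio = rejection_ratio(self.scores, t)
        return report


def run_cohort(patients: list[PhantomPatient], coarse: CoarseUNet,
               rejection: RejectionNet, segmenter: PromptSegmenter,
               gate_cfg: GateConfig, manual_ratio: float = 0.4,
               expansion_ratio: float = 0.4,
               match_cfg: LesionMatchConfig = LesionMatchConfig(),
               batch_size: int = 16) -> tuple[list[CascadeResult], EvalReport]:
    """Evaluate the cascade on a patient list at one gate threshold.

    Manual interaction is simulated from ground truth (expanded ground-truth
    component boxes), mirroring how user input is emulated throughout.
    """
    if not patients:
        raise ValueError("empty test split")
    cache = _CohortCache(patients, coarse, rejection, segmenter,
                         manual_ratio, expansion_ratio, batch_size)
    return cache.results_at(gate_cfg.threshold), cache.report_at(
        gate_cfg.threshold, match_cfg)


def sweep_thresholds(patients: list[PhantomPatient], coarse: CoarseUNet,
                     rejection: RejectionNet, segmenter: PromptSegmenter,
                     t_grid, manual_ratio: float = 0.4,
                     expansion_ratio: float = 0.4,
                     batch_size: int = 16) -> list[dict]:
    """Threshold sweep reusing a single coarse/rejection/fine pass.

    Returns one record per threshold: rejection ratio (non-decreasing along
    the sorted grid), mean DSC and mean 95% HD.
    """
    t_grid = list(t_grid)
    if any(b < a for a, b in zip(t_grid, t_grid[1:])):
        raise ValueError("t_grid must be sorted ascending")
    cache = _CohortCache(patients, coarse, rejection, segmenter,
                         manual_ratio, expansion_ratio, batch_size)
    records = []
    for t in t_grid:
        rep = cache.report_at(t)
        records.append({"t": float(t),
                        "rejection_ratio": rep.rejection_ratio,
                        "mean_dsc": rep.dsc_mean,
                        "mean_hd95": rep.hd95_mean})
    return records


def results_to_frame(results: list[CascadeResult]) -> pd.DataFrame:
    """Per-slice score/decision table (patient, slice, s_i, d_i, decision)."""
    return pd.DataFrame([{
        "patient_id": r.patient_id, "slice_index": r.slice_index,
        "score": r.score, "target_dice": r.target_dice,
        "decision": r.decision.value,
        "n_boxes": len(r.boxes),
    } for r in results])


def report_to_json(report: EvalReport, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
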