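"""Region-grouped F-measure evaluation and the method-comparison harness.

Predictions and ground truth are BRATS label rasters; scores are
reported for the three nested regions WT = {1, 2, 4}, TC = {1, 4} and
ET = {4}. Empty-region convention: if prediction and ground truth are
both empty the F-measure is 1, if exactly one is empty it is 0.
Cohort standard deviations use the population (n) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EvaluationError
from .preprocess import BRATS_LABELS

#: region name -> BRATS label set.
REGION_LABELS = {"WT": (1, 2, 4), "TC": (1, 4), "ET": (4,)}
REGION_NAMES = tuple(REGION_LABELS)


def f_measure(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Harmonic mean of pixel precision and recall of two boolean masks."""
    pred = np.asarray(pred_mask, dtype=bool)
    gt = np.asarray(gt_mask, dtype=bool)
    if pred.shape != gt.shape:
        raise EvaluationError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    np_pred, np_gt = pred.sum(), gt.sum()
    if np_pred == 0 and np_gt == 0:
        return 1.0
    if np_pred == 0 or np_gt == 0:
        return 0.0
    tp = np.logical_and(pred, gt).sum()
    if tp == 0:
        return 0.0
    return float(2.0 * tp / (np_pred + np_gt))


def region_mask(labels: np.ndarray, region: str) -> np.ndarray:
    """Boolean mask of a WT/TC/ET region from a BRATS label raster."""
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), BRATS_LABELS)
    if bad.size:
        raise EvaluationError(f"labels outside BRATS space: {bad.tolist()}")
    if region not in REGION_LABELS:
        raise EvaluationError(f"unknown region {region!r}")
    return np.isin(labels, REGION_LABELS[region])


@dataclass
class CohortMetrics:
    """Per-subject and aggregated F-measures, keyed by region."""

    per_subject: dict  # region -> list of per-subject F
    mean: dict  # region -> float
    std: dict  # region -> float (population)

    def as_table(self) -> str:
        header = "region  mean    std"
        rows = [
            f"{r:6s}  {self.mean[r]:.4f}  {self.std[r]:.4f}" for r in REGION_NAMES
        ]
        return "\n".join([header, *rows])


def evaluate_cohort(
    pred_maps: dict[str, np.ndarray], gt_maps: dict[str, np.ndarray]
) -> CohortMetrics:
    """Per-subject F per region, with mean and population std across subjects."""
    if set(pred_maps) != set(gt_maps):
        raise EvaluationError(
            f"mismatched subject sets: {sorted(set(pred_maps) ^ set(gt_maps))}"
        )
    if not pred_maps:
        raise EvaluationError("empty cohort")
    subject_ids = sorted(pred_maps)
    per_subject = {r: [] for r in REGION_NAMES}
    for sid in subject_ids:
        for r in REGION_NAMES:
            per_subject[r].append(
                f_measure(region_mask(pred_maps[sid], r), region_mask(gt_maps[sid], r))
            )
    mean = {r: float(np.mean(v)) for r, v in per_subject.items()}
    std = {r: float(np.std(v)) for r, v in per_subject.items()}
    return CohortMetrics(per_subject=per_subject, mean=mean, std=std)


def compare_methods(
    preds_a: dict[str, np.ndarray],
    preds_b: dict[str, np.ndarray],
    gt_maps: dict[str, np.ndarray],
    name_a: str = "net_only",
    name_b: str = "hybrid",
) -> dict:
    """Paired per-subject comparison of two methods on one test cohort.

    Returns per-method CohortMetrics plus the per-region mean of the
    paired per-subject differences (B minus A). No significance test.
    """
    if set(preds_a) != set(preds_b):
        raise EvaluationError("methods evaluated on different subject sets")
    metrics_a = evaluate_cohort(preds_a, gt_maps)
    metrics_b = evaluate_cohort(preds_b, gt_maps)
    diff = {
        r: float(
            np.mean(
                np.array(metrics_b.per_subject[r]) - np.array(metrics_a.per_subject[r])
            )
        )
        for r in REGION_NAMES
    }
    return {
        "methods": {name_a: metrics_a, name_b: metrics_b},
        "mean_difference": diff,
    }
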