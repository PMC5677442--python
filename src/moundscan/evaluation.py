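"""Detection-accuracy bookkeeping.

Detections are matched one-to-one to ground-truth mounds by centroid
proximity; the resulting counts follow the field-survey convention: a
matched mound is a True Positive (TP), an unmatched truth mound a False
Negative (FN), and an unmatched detection a False Positive (FP).  The
single quality score is

    accuracy = TP / (TP + FN + FP),

computed per ROI and pooled over all ROIs for the report's Total row.
Note the pooled accuracy is generally NOT the mean of per-ROI accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EvalCounts", "match_detections", "accuracy_eq6", "aggregate_report"]


@dataclass
class EvalCounts:
    """TP/FN/FP tallies for one ROI (samples = mounds present = TP + FN)."""

    samples: int
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.samples, self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fn != self.samples:
            raise ValueError("samples must equal tp + fn")

    @property
    def accuracy(self) -> float:
        return accuracy_eq6(self.tp, self.fn, self.fp)


def accuracy_eq6(tp: int, fn: int, fp: int) -> float:
    """Detection accuracy TP / (TP + FN + FP), in [0, 1]."""
    if min(tp, fn, fp) < 0:
        raise ValueError("counts must be non-negative")
    denom = tp + fn + fp
    if denom == 0:
        raise ValueError("accuracy undefined for all-zero counts")
    return tp / denom


def _detection_centroid(det) -> tuple[float, float]:
    if hasattr(det, "soil_contour"):
        return det.soil_contour.centroid
    if hasattr(det, "centroid"):
        return tuple(det.centroid)
    return float(det[0]), float(det[1])


def match_detections(
    detections: list,
    truth,
    max_centroid_dist_px: float | None = None,
) -> EvalCounts:
    """Greedy one-to-one matching of detections to truth mounds.

    Candidate pairs are taken in order of ascending centroid distance; a
    detection claims an unmatched truth mound if it lies within the
    distance budget.  The budget defaults to 1.5x that mound's core major
    axis, mirroring visual co-location without any overlap computation.

    ``detections`` may be Detection objects, objects with a ``centroid``
    attribute, or bare (row, col) pairs.
    """
    truth_entries = truth.entries if hasattr(truth, "entries") else list(truth)
    det_centroids = [_detection_centroid(d) for d in detections]

    pairs = []
    for ti, entry in enumerate(truth_entries):
        budget = (
            max_centroid_dist_px
            if max_centroid_dist_px is not None
            else 1.5 * entry.major_axis_px
        )
        tc = entry.centroid
        for di, dc in enumerate(det_centroids):
            d = float(np.hypot(tc[0] - dc[0], tc[1] - dc[1]))
            if d <= budget:
                pairs.append((d, ti, di))
    pairs.sort()

    matched_t: set[int] = set()
    matched_d: set[int] = set()
    for _, ti, di in pairs:
        if ti in matched_t or di in matched_d:
            continue
        matched_t.add(ti)
        matched_d.add(di)

    tp = len(matched_t)
    fn = len(truth_entries) - tp
    fp = len(det_centroids) - len(matched_d)
    return EvalCounts(samples=len(truth_entries), tp=tp, fn=fn, fp=fp)


def aggregate_report(
    per_roi: list[EvalCounts], roi_ids: list[str] | None = None
) -> pd.DataFrame:
    """Tabulate per-ROI counts plus pooled Total and Proportion rows.

    The Total row sums the counts and applies the accuracy formula to the
    sums; the Proportion row expresses TP/FN/FP as percentages of the total
    number of mounds present.  Percentages are rounded to one decimal.
    """
    if not per_roi:
        raise ValueError("need at least one ROI")
    if roi_ids is None:
        roi_ids = [str(i + 1) for i in range(len(per_roi))]
    rows = []
    for roi_id, ec in zip(roi_ids, per_roi):
        denom = ec.tp + ec.fn + ec.fp
        acc = round(100.0 * ec.accuracy, 1) if denom > 0 else float("nan")
        rows.append(
            {
                "ROI": roi_id,
                "Termite Mounds": ec.samples,
                "True Positives": ec.tp,
                "False Negatives": ec.fn,
                "False Positives": ec.fp,
                "Accuracy (%)": acc,
            }
        )
    tot_samples = sum(ec.samples for ec in per_roi)
    tot_tp = sum(ec.tp for ec in per_roi)
    tot_fn = sum(ec.fn for ec in per_roi)
    tot_fp = sum(ec.fp for ec in per_roi)
    rows.append(
        {
            "ROI": "Total",
            "Termite Mounds": tot_samples,
            "True Positives": tot_tp,
            "False Negatives": tot_fn,
            "False Positives": tot_fp,
            "Accuracy (%)": round(100.0 * accuracy_eq6(tot_tp, tot_fn, tot_fp), 1)
            if tot_tp + tot_fn + tot_fp > 0
            else float("nan"),
        }
    )
    if tot_samples > 0:
        rows.append(
            {
                "ROI": "Proportion",
                "Termite Mounds": "100%",
                "True Positives": f"{round(100.0 * tot_tp / tot_samples, 1)}%",
                "False Negatives": f"{round(100.0 * tot_fn / tot_samples, 1)}%",
                "False Positives": f"{round(100.0 * tot_fp / tot_samples, 1)}%",
                "Accuracy (%)": "",
            }
        )
    return pd.DataFrame(rows)


def report_to_csv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False)
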