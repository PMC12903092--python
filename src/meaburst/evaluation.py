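"""Scoring detections against planted ground truth.

Matching is by interval overlap: a detected burst matches a planted one when
their overlap covers at least half of the planted interval (greedy, left to
right, one-to-one). Precision/recall/F1 are computed over main bursts;
classification accuracy is the fraction of matched bursts (any class) whose
main/fragment label agrees with the planted class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from meaburst.network_bursts import NetworkBurst
from meaburst.synthetic import GroundTruth

__all__ = ["DetectionScore", "match_intervals", "score_detection"]


@dataclass(frozen=True)
class DetectionScore:
    precision: float
    recall: float
    f1: float
    mean_boundary_error: float  # seconds, over matched main bursts
    class_accuracy: float  # over matched bursts of any class
    n_true: int
    n_detected: int


def match_intervals(
    truth: Sequence[tuple[float, float]],
    detected: Sequence[tuple[float, float]],
    min_overlap_frac: float = 0.5,
) -> list[tuple[int, int]]:
    """One-to-one greedy matching of planted to detected intervals.

    A pair qualifies when the overlap is at least ``min_overlap_frac`` of the
    planted interval's length. Returns (truth_index, detected_index) pairs.
    """
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, (ts, te) in enumerate(truth):
        best, best_ov = None, 0.0
        for j, (ds, de) in enumerate(detected):
            if j in used:
                continue
            ov = min(te, de) - max(ts, ds)
            if ov >= min_overlap_frac * (te - ts) and ov > best_ov:
                best, best_ov = j, ov
        if best is not None:
            used.add(best)
            pairs.append((i, best))
    return pairs


def score_detection(truth: GroundTruth, detected: Sequence[NetworkBurst]) -> DetectionScore:
    """Score classified detections of one well against its planted truth."""
    true_mains = truth.mains()
    det_mains = [(b.start, b.end) for b in detected if b.klass == "main"]
    pairs = match_intervals(true_mains, det_mains)
    tp = len(pairs)
    precision = tp / len(det_mains) if det_mains else (1.0 if not true_mains else 0.0)
    recall = tp / len(true_mains) if true_mains else 1.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    if pairs:
        errs = []
        for i, j in pairs:
            ts, te = true_mains[i]
            ds, de = det_mains[j]
            errs.append((abs(ds - ts) + abs(de - te)) / 2)
        boundary = sum(errs) / len(errs)
    else:
        boundary = float("nan")
    # class accuracy over ALL planted bursts matched to any detection
    all_truth = [(a, b) for a, b, _ in truth.network_bursts]
    all_det = [(b.start, b.end) for b in detected]
    all_pairs = match_intervals(all_truth, all_det)
    if all_pairs:
        agree = sum(
            truth.network_bursts[i][2] == detected[j].klass for i, j in all_pairs
        )
        class_acc = agree / len(all_pairs)
    else:
        class_acc = float("nan")
    return DetectionScore(precision=precision, recall=recall, f1=f1,
                          mean_boundary_error=boundary, class_accuracy=class_acc,
                          n_true=len(true_mains), n_detected=len(det_mains))
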