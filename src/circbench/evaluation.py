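"""Accuracy metrics for back-splice junction predictions against truth.

Sensitivity S = TP / |truth|, precision P = TP / #detected and
F1 = 2PS / (P + S) are computed in full precision and rounded only at
report time (two decimals for percentages and F1).  Threshold-swept
precision–recall curves are integrated by the trapezoid rule over the
observed recall range, with no extrapolation to recall 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


def _junction_key(rec, strict_strand: bool) -> tuple:
    if strict_strand:
        return (rec.chrom, rec.start, rec.end, rec.strand)
    return (rec.chrom, rec.start, rec.end)


@dataclass(frozen=True)
class ConfusionCounts:
    """Detected / true-positive / truth-size counts with derived metrics.

    Sensitivity and precision are ``None`` when their denominators are
    zero (empty truth, or no predictions passing the filter)."""

    n_truth: int
    n_detected: int
    n_tp: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_tp <= self.n_detected):
            raise ValueError("need 0 <= TP <= detected")
        if self.n_truth and self.n_tp > self.n_truth:
            raise ValueError("TP exceeds truth size")

    @property
    def sensitivity(self) -> float | None:
        return self.n_tp / self.n_truth if self.n_truth else None

    @property
    def precision(self) -> float | None:
        return self.n_tp / self.n_detected if self.n_detected else None

    @property
    def f1(self) -> float | None:
        p, s = self.precision, self.sensitivity
        if p is None or s is None or (p + s) == 0:
            return None
        return 2 * p * s / (p + s)

    def report(self) -> dict:
        """Display-rounded metrics: percentages and F1 to two decimals."""
        s, p, f1 = self.sensitivity, self.precision, self.f1
        return {
            "n_truth": self.n_truth,
            "n_detected": self.n_detected,
            "n_tp": self.n_tp,
            "sensitivity_pct": None if s is None else round(100 * s, 2),
            "precision_pct": None if p is None else round(100 * p, 2),
            "f1": None if f1 is None else round(f1, 2),
        }


@dataclass(frozen=True)
class PRCurve:
    """Precision–recall points swept over the minimum-support threshold."""

    points: tuple[tuple[int, float, float], ...]  # (threshold, precision, recall)
    auc: float

    @property
    def max_recall(self) -> float:
        return max((r for _, _, r in self.points), default=0.0)


def match_predictions(
    preds: Sequence,
    truth: Sequence,
    tolerance_bp: int = 0,
    strict_strand: bool = False,
) -> set[int]:
    """Indices of predictions matching some truth junction.

    A prediction matches iff a truth junction on the same chromosome (and
    strand, if strict) satisfies ``|Δstart| <= tolerance`` and
    ``|Δend| <= tolerance``.  A truth junction may satisfy many
    predictions; each prediction matches at most once.
    """
    if tolerance_bp == 0:
        truth_keys = {_junction_key(t, strict_strand) for t in truth}
        return {
            i for i, p in enumerate(preds) if _junction_key(p, strict_strand) in truth_keys
        }
    by_chrom: dict = {}
    for t in truth:
        by_chrom.setdefault(t.chrom, []).append(t)
    matched = set()
    for i, p in enumerate(preds):
        for t in by_chrom.get(p.chrom, ()):
            if strict_strand and t.strand != p.strand:
                continue
            if abs(t.start - p.start) <= tolerance_bp and abs(t.end - p.end) <= tolerance_bp:
                matched.add(i)
                break
    return matched


def confusion(
    preds: Sequence,
    truth: Sequence,
    min_support: int = 2,
    tolerance: int = 0,
    strict_strand: bool = False,
) -> ConfusionCounts:
    """Filter predictions at ``support >= min_support`` and count matches.

    TP counts distinct truth junctions recovered, so duplicate predictions
    of one junction (possible at tolerance > 0) are not double-counted."""
    detected = [p for p in preds if p.support >= min_support]
    matched_idx = match_predictions(detected, truth, tolerance, strict_strand)
    matched_truth = set()
    if tolerance == 0:
        truth_keys = {_junction_key(t, strict_strand) for t in truth}
        for i in matched_idx:
            matched_truth.add(_junction_key(detected[i], strict_strand))
    else:
        for i in matched_idx:
            p = detected[i]
            for t in truth:
                if t.chrom != p.chrom:
                    continue
                if strict_strand and t.strand != p.strand:
                    continue
                if abs(t.start - p.start) <= tolerance and abs(t.end - p.end) <= tolerance:
                    matched_truth.add(_junction_key(t, strict_strand))
    n_tp = min(len(matched_idx), len(matched_truth)) if truth else len(matched_idx)
    return ConfusionCounts(n_truth=len(truth), n_detected=len(detected), n_tp=n_tp)


def confusion_from_counts(n_detected: int, n_tp: int, n_truth: int) -> ConfusionCounts:
    """Build the confusion summary directly from published integer counts."""
    return ConfusionCounts(n_truth=n_truth, n_detected=n_detected, n_tp=n_tp)


def pr_curve(preds: Sequence, truth: Sequence, tolerance: int = 0) -> PRCurve:
    """Sweep the support threshold t = 1..max observed support.

    At each t, predictions with ``support >= t`` are scored; the AUC is the
    trapezoidal integral of precision over recall after sorting points by
    recall ascending.  The left edge is closed by carrying the precision of
    the lowest-recall point down to recall 0 (so a perfect predictor has
    AUC equal to its recall at t = 1); there is no extrapolation beyond the
    maximum observed recall.  Empty predictions give an empty curve, AUC 0.
    """
    if not preds or not truth:
        return PRCurve(points=(), auc=0.0)
    max_support = max(p.support for p in preds)
    points = []
    for t in range(1, max_support + 1):
        cc = confusion(preds, truth, min_support=t, tolerance=tolerance)
        if cc.precision is None:
            continue
        points.append((t, cc.precision, cc.sensitivity))
    if not points:
        return PRCurve(points=(), auc=0.0)
    by_recall = sorted(points, key=lambda x: (x[2], x[1]))
    recalls = np.array([0.0] + [r for _, _, r in by_recall])
    precisions = np.array([by_recall[0][1]] + [p for _, p, _ in by_recall])
    auc = float(np.trapezoid(precisions, recalls))
    return PRCurve(points=tuple(points), auc=auc)


def background_summary(preds: Sequence, min_support: int = 2) -> tuple[int, int]:
    """(candidate count, total junction read count) after support filtering.

    On truth-free background data this summarizes false positives."""
    detected = [p for p in preds if p.support >= min_support]
    return len(detected), sum(p.support for p in detected)


def delta_metrics(
    counts_a: ConfusionCounts, counts_b: ConfusionCounts
) -> tuple[float | None, float | None]:
    """(ΔP, ΔS) in percentage points, b minus a, differencing the
    two-decimal display-rounded operands (so printed deltas reproduce)."""
    if counts_a.n_truth != counts_b.n_truth:
        raise ValueError("confusion counts computed against different truth sizes")

    def diff(x, y):
        if x is None or y is None:
            return None
        return round(round(100 * y, 2) - round(100 * x, 2), 2)

    return (
        diff(counts_a.precision, counts_b.precision),
        diff(counts_a.sensitivity, counts_b.sensitivity),
    )
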