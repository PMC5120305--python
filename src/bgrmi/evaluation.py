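"""Precision-recall benchmarking of inferred networks.

All scoreable (regulator, target) pairs — the product of the gold
standard's universes, self-pairs excluded — are ranked by score.  One
PR point is produced per unique score (ties grouped), and the area
under the curve follows the Davis-Goadrich interpolation: between two
operating points, intermediate points are inserted at every unit
true-positive increment with the false-positive count interpolated
linearly (placing them on the hyperbola precision traces between the
ends), and the area is the trapezoidal sum over the densified point
sequence.  The segment leaving the zero-recall origin is a rectangle
at its endpoint's precision, since precision is undefined before the
first prediction.  Pairs absent from the score map count as score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GoldStandard

__all__ = ["PRCurve", "pr_curve", "aupr"]


@dataclass
class PRCurve:
    """PR operating points (one per unique score, descending) and the AUPR."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    aupr: float
    n_positive: int
    n_pairs: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing along the curve")
        if np.any((self.precision < 0) | (self.precision > 1)):
            raise ValueError("precision out of [0, 1]")


def _segment_area(tp0: float, fp0: float, tp1: float, fp1: float, n_pos: int) -> float:
    """Area between two PR operating points under Davis-Goadrich
    interpolation, in recall units.

    Intermediate points are placed at each integer TP between the
    ends, with FP growing linearly in TP, and consecutive points are
    connected by straight lines (trapezoids).  When the segment leaves
    the origin (no predictions yet) its first slice is a rectangle at
    the slice endpoint's precision.
    """
    d_tp = int(round(tp1 - tp0))
    if d_tp == 0:
        return 0.0
    d_fp = fp1 - fp0
    area = 0.0
    prev_prec = tp0 / (tp0 + fp0) if tp0 + fp0 > 0 else None
    for k in range(1, d_tp + 1):
        tp = tp0 + k
        fp = fp0 + d_fp * k / d_tp
        prec = tp / (tp + fp)
        if prev_prec is None:
            area += prec          # rectangle out of the origin
        else:
            area += 0.5 * (prev_prec + prec)
        prev_prec = prec
    return float(area / n_pos)


def pr_curve(
    scores: dict[tuple[str, str], float],
    gold: GoldStandard,
) -> PRCurve:
    """Precision-recall curve of a scored edge map against a gold standard."""
    if len(gold.edges) == 0:
        raise ValueError("AUPR undefined: gold standard has no positive edges")
    pairs = [
        (reg, tgt)
        for reg in sorted(gold.regulator_universe)
        for tgt in sorted(gold.target_universe)
        if reg != tgt
    ]
    if not pairs:
        raise ValueError("no scoreable pairs")
    unknown = set(scores) - set(pairs)
    unknown = {p for p in unknown if p[0] != p[1]}  # self-pairs silently ignored
    if unknown:
        raise ValueError(f"scored pairs outside gold universes: {sorted(unknown)[:5]}")
    s = np.array([scores.get(p, 0.0) for p in pairs])
    labels = np.array([p in gold.edges for p in pairs], dtype=bool)
    n_pos = int(labels.sum())

    order = np.argsort(-s, kind="stable")
    s_sorted, labels_sorted = s[order], labels[order]
    uniq = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])  # last index of each tie group
    tp_cum = np.cumsum(labels_sorted)
    tp = tp_cum[uniq].astype(float)
    fp = (uniq + 1) - tp
    thresholds = s_sorted[uniq]
    precision = tp / (tp + fp)
    recall = tp / n_pos

    area = 0.0
    prev_tp, prev_fp = 0.0, 0.0
    for t, f in zip(tp, fp):
        area += _segment_area(prev_tp, prev_fp, t, f, n_pos)
        prev_tp, prev_fp = t, f
    return PRCurve(thresholds, precision, recall, float(area), n_pos, len(pairs))


def aupr(curve_or_scores, gold: GoldStandard | None = None) -> float:
    """Area under the PR curve; accepts a PRCurve or a raw score map."""
    if isinstance(curve_or_scores, PRCurve):
        return curve_or_scores.aupr
    if gold is None:
        raise ValueError("gold standard required when passing raw scores")
    return pr_curve(curve_or_scores, gold).aupr
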