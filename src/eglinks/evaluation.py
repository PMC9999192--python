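"""Precision-recall evaluation of E/G predictions against reference sets.

Scored predictions yield a full precision-recall curve and its AUPR
(step-wise / average-precision integration).  Already-thresholded
(binary) predictions yield a single point: precision plus two recall
variants — *pessimistic* (TP over all reference positives) and
*optimistic* (TP over only those reference positives present in the
prediction universe, i.e. the pairs the predictor could have called).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .io_core import (
    CandidatePair,
    GeneAnnotation,
    GenomicInterval,
    ReferenceSet,
    intersect_with_catalog,
)

__all__ = [
    "PRCurve",
    "PointMetrics",
    "PredictionRecord",
    "pr_curve",
    "aupr",
    "point_metrics",
    "evaluate_predictions",
]


@dataclass
class PRCurve:
    """Ordered (threshold, precision, recall) points of a PR sweep."""

    points: List[Tuple[float, float, float]]
    positives: int
    negatives: int

    def __post_init__(self) -> None:
        recalls = [r for _, _, r in self.points]
        if any(b < a for a, b in zip(recalls, recalls[1:])):
            raise ValueError("recall must be non-decreasing along the sweep")
        if any(not (0 <= p <= 1 and 0 <= r <= 1) for _, p, r in self.points):
            raise ValueError("precision and recall must lie in [0, 1]")


@dataclass
class PointMetrics:
    """Confusion counts with precision and the two recall variants.

    Percentages are rounded for reporting (precision to 1 decimal,
    recalls to 2) while the ``*_raw`` fields keep full precision.  A
    zero denominator yields the ``nan`` sentinel.
    """

    tp: int
    n_predicted: int
    gp_pes: int
    gp_opt: int
    precision_pct: float
    recall_pes_pct: float
    recall_opt_pct: float
    precision_raw: float
    recall_pes_raw: float
    recall_opt_raw: float


def pr_curve(scored: Sequence[CandidatePair], score_name: str) -> PRCurve:
    """Precision-recall curve over a labeled, scored candidate set.

    Thresholds sweep the distinct score values in descending order; all
    pairs tied at a threshold enter together.  At each threshold,
    precision = TP/(TP+FP) and recall = TP/P over pairs scoring >= the
    threshold.
    """
    labels = []
    scores = []
    for p in scored:
        if p.label not in (0, 1):
            raise ValueError(
                f"pair ({p.element_id}, {p.gene_id}) lacks a 0/1 label"
            )
        s = p.scores.get(score_name)
        if s is None or math.isnan(s):
            raise ValueError(
                f"pair ({p.element_id}, {p.gene_id}) lacks score {score_name!r}"
            )
        labels.append(p.label)
        scores.append(s)
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0:
        raise ValueError("no ground positives: recall undefined")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    # last index of each tied block = threshold boundary
    boundary = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    points = [
        (
            float(s_sorted[i]),
            float(tp_cum[i] / (tp_cum[i] + fp_cum[i])),
            float(tp_cum[i] / n_pos),
        )
        for i in boundary
    ]
    return PRCurve(points=points, positives=n_pos, negatives=n_neg)


def aupr(curve: PRCurve) -> float:
    """Area under the PR curve by step-wise (average-precision) integration.

    Each threshold contributes (recall increment) x (precision at that
    threshold); ties in score enter as one block.  Equals average
    precision; bounded by [0, 1].
    """
    area = 0.0
    prev_recall = 0.0
    for _, precision, recall in curve.points:
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def _pct(numerator: float, denominator: float, decimals: int) -> Tuple[float, float]:
    if denominator == 0:
        return (math.nan, math.nan)
    raw = 100.0 * numerator / denominator
    return (round(raw, decimals), raw)


def point_metrics(
    tp: int, n_predicted: int, gp_pes: int, gp_opt: int
) -> PointMetrics:
    """Precision and pessimistic/optimistic recall from confusion counts.

    precision = tp / n_predicted (reported to 1 decimal, in %);
    recall_pes = tp / gp_pes and recall_opt = tp / gp_opt (each reported
    to 2 decimals, in %).  Zero denominators give the nan sentinel.
    """
    if min(tp, n_predicted, gp_pes, gp_opt) < 0:
        raise ValueError("counts must be >= 0")
    if tp > n_predicted:
        raise ValueError(f"tp ({tp}) cannot exceed n_predicted ({n_predicted})")
    precision_pct, precision_raw = _pct(tp, n_predicted, 1)
    recall_pes_pct, recall_pes_raw = _pct(tp, gp_pes, 2)
    recall_opt_pct, recall_opt_raw = _pct(tp, gp_opt, 2)
    return PointMetrics(
        tp=tp,
        n_predicted=n_predicted,
        gp_pes=gp_pes,
        gp_opt=gp_opt,
        precision_pct=precision_pct,
        recall_pes_pct=recall_pes_pct,
        recall_opt_pct=recall_opt_pct,
        precision_raw=precision_raw,
        recall_pes_raw=recall_pes_raw,
        recall_opt_raw=recall_opt_raw,
    )


@dataclass
class PredictionRecord:
    """One coordinate-space prediction: an enhancer span, a promoter span,
    and whether the predictor called the pair positive."""

    enhancer: GenomicInterval
    promoter: GenomicInterval
    predicted: bool


def _map_to_reference_ids(
    predictions: Sequence[PredictionRecord],
    ccres: Sequence[GenomicInterval],
    genes: Mapping[str, GeneAnnotation],
) -> List[Set[Tuple[str, str]]]:
    """Per prediction, the (catalog id, gene id) pairs it resolves to.

    The enhancer span maps to every overlapping catalog entry; the
    promoter span maps to every gene with a TSS inside it.
    """
    enhancer_hits = intersect_with_catalog(
        [p.enhancer for p in predictions], ccres
    )
    mapped: List[Set[Tuple[str, str]]] = []
    for pred, eids in zip(predictions, enhancer_hits):
        gids = {
            gid
            for gid, g in genes.items()
            if g.chrom == pred.promoter.chrom
            and any(pred.promoter.start <= t < pred.promoter.end for t in g.tss_list)
        }
        mapped.append({(e, g) for e in eids for g in gids})
    return mapped


def evaluate_predictions(
    predictions: Sequence[PredictionRecord],
    reference: ReferenceSet,
    ccres: Sequence[GenomicInterval],
    genes: Mapping[str, GeneAnnotation],
) -> PointMetrics:
    """Point metrics of thresholded coordinate-space predictions.

    Each prediction is mapped to (catalog id, gene id) pairs by interval
    overlap.  TP = distinct positive-predicted pairs labeled 1 in the
    reference; n_predicted = distinct positive-predicted pairs present
    in the reference (either label); gp_pes = all reference positives;
    gp_opt = reference positives present among the pairs mapped from any
    prediction (the predictor's universe).
    """
    if len(reference) == 0:
        raise ValueError("empty reference set")
    mapped = _map_to_reference_ids(predictions, ccres, genes)

    universe: Set[Tuple[str, str]] = set()
    called: Set[Tuple[str, str]] = set()
    for pred, pairs in zip(predictions, mapped):
        universe |= pairs
        if pred.predicted:
            called |= pairs

    ref_positives = reference.positives
    in_reference = {k for k in called if k in reference}
    tp = len(in_reference & ref_positives)
    return point_metrics(
        tp=tp,
        n_predicted=len(in_reference),
        gp_pes=len(ref_positives),
        gp_opt=len(ref_positives & universe),
    )


def pr_table(curve: PRCurve) -> "np.ndarray":
    """Curve points as a (n, 3) array: threshold, precision, recall."""
    return np.asarray(curve.points, dtype=float)
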