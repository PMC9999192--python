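"""Enhancer/gene scoring methods.

Five procedures that attach a score to candidate (element, gene) pairs:

* **distance** — inverse of the smallest element-to-TSS distance;
* **Sheffield** — Pearson correlation between log10 chromatin
  accessibility at the element and log10 expression of the gene across
  cell types;
* **Average-Rank** — inverse of the mean of the ranks assigned by the
  distance and Sheffield methods;
* **ABC (Activity-By-Contact)** — the product of an element's activity
  (geometric mean of accessibility and H3K27ac read counts) and its
  contact with the gene, normalized over all candidate elements in a
  window around the gene;
* **open-chromatin correlation caller** — pairwise correlation of
  normalized log10 accessibility between nearby consensus peaks, with
  TSS-anchored pairs reported as E/G calls.

Inverse-distance scores use a 1 bp floor so an element overlapping a TSS
gets score 1 rather than a division by zero.  Undefined correlations
(zero-variance vectors) are carried as ``nan`` and rank below every
defined value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io_core import (
    CandidatePair,
    GeneAnnotation,
    GenomicInterval,
    SignalMatrix,
    interval_gap,
    merge_intervals,
    min_tss_distance,
)

__all__ = [
    "ABCElement",
    "ContactModel",
    "CorrelationCallConfig",
    "CorrelationCallResult",
    "score_distance",
    "score_sheffield",
    "score_average_rank",
    "abc_activity",
    "abc_contact",
    "score_abc",
    "filter_expressed_genes",
    "call_correlation_pairs",
]

#: Floor (bp) applied to distances before inversion, so that elements
#: overlapping a TSS score 1.0 instead of dividing by zero.
DISTANCE_FLOOR_BP = 1


@dataclass
class ABCElement:
    """A candidate element with the two read counts that define activity."""

    interval: GenomicInterval
    accessibility_count: float
    h3k27ac_count: float

    def __post_init__(self) -> None:
        if self.accessibility_count < 0 or self.h3k27ac_count < 0:
            raise ValueError("ABC read counts must be >= 0")

    @property
    def element_id(self) -> str:
        iv = self.interval
        return iv.id if iv.id is not None else f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass
class ContactModel:
    """Element-gene contact: a normalized contact table or 1/distance decay.

    ``distance_decay`` implements the fractal-globule approximation
    C = 1 / max(distance, d_floor); ``table`` looks contacts up by
    (element id, gene id), defaulting to 0 for absent pairs.
    """

    mode: str = "distance_decay"
    table: Optional[Mapping[Tuple[str, str], float]] = None
    d_floor: float = DISTANCE_FLOOR_BP

    def __post_init__(self) -> None:
        if self.mode not in ("distance_decay", "table"):
            raise ValueError(f"unknown contact mode {self.mode!r}")
        if self.mode == "table":
            if self.table is None:
                raise ValueError("table mode requires a contact table")
            if any(v < 0 for v in self.table.values()):
                raise ValueError("contact values must be >= 0")


@dataclass
class CorrelationCallConfig:
    """Tuning of the open-chromatin pairwise-correlation caller."""

    max_pair_distance: float = 500_000
    r_threshold: float = 0.7
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_pair_distance <= 0:
            raise ValueError("max_pair_distance must be > 0")
        if not -1 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must lie in [-1, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------


def score_distance(
    pairs: Sequence[CandidatePair],
    genes: Mapping[str, GeneAnnotation],
    d_floor: float = DISTANCE_FLOOR_BP,
) -> List[CandidatePair]:
    """Attach ``distance_score`` = 1 / max(min TSS distance, d_floor)."""
    for p in pairs:
        if p.gene_id not in genes:
            raise KeyError(f"gene {p.gene_id!r} absent from annotation")
        d = min_tss_distance(p.element, genes[p.gene_id])
        if math.isinf(d):
            raise ValueError(
                f"pair ({p.element_id}, {p.gene_id}): element and gene on "
                "different chromosomes"
            )
        p.set_score("distance_score", 1.0 / max(d, d_floor))
    return list(pairs)


# ---------------------------------------------------------------------------
# Sheffield correlation
# ---------------------------------------------------------------------------


def _pearson_with_stats(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Pearson r, two-sided p (t approximation) and Fisher Z for two vectors.

    Returns (nan, nan, nan) when either vector has zero variance.
    """
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan, math.nan)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    r2 = min(r * r, 1 - 1e-15)
    t = r * math.sqrt((n - 2) / (1 - r2))
    p = 2 * float(stats.t.sf(abs(t), n - 2))
    z = math.atanh(max(-1 + 1e-15, min(1 - 1e-15, r))) * math.sqrt(max(n - 3, 0))
    return (r, p, z)


def score_sheffield(
    pairs: Sequence[CandidatePair],
    accessibility: SignalMatrix,
    expression: SignalMatrix,
    pseudocount: float = 1.0,
) -> List[CandidatePair]:
    """Attach ``correlation``: Pearson r of log10(signal + pseudocount).

    The accessibility and expression matrices must share an identical
    ordered cell-type list of at least 3 cell types.  A zero-variance
    vector on either side yields the ``nan`` sentinel (undefined
    correlation).  A two-sided p-value and Fisher Z-score are reported
    alongside r, but only r drives downstream ranking.
    """
    if accessibility.cell_types != expression.cell_types:
        raise ValueError("accessibility and expression cell types differ")
    if len(accessibility.cell_types) < 3:
        raise ValueError("need at least 3 cell types for correlation")
    for p in pairs:
        x = np.log10(accessibility.row(p.element_id) + pseudocount)
        y = np.log10(expression.row(p.gene_id) + pseudocount)
        r, pval, z = _pearson_with_stats(x, y)
        p.set_score("correlation", r)
        p.set_score("correlation_p", pval)
        p.set_score("correlation_z", z)
    return list(pairs)


# ---------------------------------------------------------------------------
# Average-Rank
# ---------------------------------------------------------------------------


def _descending_ranks(values: Sequence[float]) -> np.ndarray:
    """Rank 1 = largest value; ties share the mean of tied positions.

    ``nan`` values (undefined scores) sort below every defined value and
    mid-rank among themselves.
    """
    arr = np.asarray(values, dtype=float)
    arr = np.where(np.isnan(arr), -np.inf, arr)
    return stats.rankdata(-arr, method="average")


def score_average_rank(pairs: Sequence[CandidatePair]) -> List[CandidatePair]:
    """Attach ``average_rank_score`` = 1 / mean(distance rank, correlation rank).

    Ranks are computed within the supplied candidate set (rank 1 = best,
    i.e. largest ``distance_score`` / largest ``correlation``).  The
    individual ranks are stored as ``distance_rank`` and
    ``correlation_rank`` for inspection.
    """
    if not pairs:
        return []
    for p in pairs:
        if "distance_score" not in p.scores or "correlation" not in p.scores:
            raise KeyError(
                f"pair ({p.element_id}, {p.gene_id}) lacks an input score"
            )
    rank_d = _descending_ranks([p.scores["distance_score"] for p in pairs])
    rank_c = _descending_ranks([p.scores["correlation"] for p in pairs])
    for p, rd, rc in zip(pairs, rank_d, rank_c):
        p.set_score("distance_rank", rd)
        p.set_score("correlation_rank", rc)
        p.set_score("average_rank_score", 1.0 / ((rd + rc) / 2.0))
    return list(pairs)


# ---------------------------------------------------------------------------
# Activity-By-Contact
# ---------------------------------------------------------------------------


def abc_activity(element: ABCElement, pseudocount: float = 0.0) -> float:
    """Activity A = geometric mean of accessibility and H3K27ac counts."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    return math.sqrt(
        (element.accessibility_count + pseudocount)
        * (element.h3k27ac_count + pseudocount)
    )


def abc_contact(
    element: ABCElement, gene: GeneAnnotation, model: ContactModel
) -> float:
    """Contact C between an element and a gene under the given model."""
    if model.mode == "table":
        return float(model.table.get((element.element_id, gene.gene_id), 0.0))
    d = min_tss_distance(element.interval, gene)
    if math.isinf(d):
        return 0.0
    return 1.0 / max(d, model.d_floor)


def score_abc(
    elements: Sequence[ABCElement],
    gene: GeneAnnotation,
    model: ContactModel,
    window: float = 5_000_000,
    pseudocount: float = 0.0,
) -> Dict[str, float]:
    """ABC score of each candidate element for one gene.

    abc_score(E, G) = A(E)*C(E,G) / sum over elements e within the window
    of A(e)*C(e,G).  The window is centered on the gene: an element
    qualifies when its smallest TSS distance is at most window/2.  Scores
    over in-window elements sum to 1 whenever any product is positive;
    an all-zero denominator yields all-zero scores.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    in_window = [
        e for e in elements if min_tss_distance(e.interval, gene) <= window / 2
    ]
    products = {
        e.element_id: abc_activity(e, pseudocount) * abc_contact(e, gene, model)
        for e in in_window
    }
    denom = sum(products.values())
    if denom <= 0:
        return {eid: 0.0 for eid in products}
    return {eid: v / denom for eid, v in products.items()}


def filter_expressed_genes(
    genes: Mapping[str, GeneAnnotation],
    threshold: float,
    expression: Optional[Mapping[str, float]] = None,
    promoter_activity: Optional[Mapping[str, float]] = None,
) -> Dict[str, GeneAnnotation]:
    """Keep genes whose expression — or, as a proxy, promoter activity —
    meets the threshold.

    For each gene the expression value is preferred when available;
    promoter activity (geometric mean of accessibility and H3K27ac at
    the promoter) stands in for genes without expression data.  A gene
    lacking both signals is an error.
    """
    kept: Dict[str, GeneAnnotation] = {}
    for gid, gene in genes.items():
        if expression is not None and gid in expression:
            signal = expression[gid]
        elif promoter_activity is not None and gid in promoter_activity:
            signal = promoter_activity[gid]
        else:
            raise KeyError(
                f"gene {gid!r} has neither expression nor promoter activity"
            )
        if signal >= threshold:
            kept[gid] = gene
    return kept


# ---------------------------------------------------------------------------
# Open-chromatin pairwise-correlation caller
# ---------------------------------------------------------------------------


@dataclass
class CorrelationCallResult:
    """Consensus peaks, their normalized signal, and the resulting E/G calls."""

    consensus_peaks: List[GenomicInterval]
    normalized: SignalMatrix
    calls: List[CandidatePair] = field(default_factory=list)


def _consensus_counts(
    consensus: Sequence[GenomicInterval],
    peaks_with_counts: Sequence[Tuple[GenomicInterval, float]],
) -> np.ndarray:
    """Aggregate one cell type's per-peak counts onto consensus peaks."""
    from intervaltree import IntervalTree

    trees: Dict[str, IntervalTree] = {}
    for idx, cp in enumerate(consensus):
        trees.setdefault(cp.chrom, IntervalTree()).addi(cp.start, cp.end, idx)
    out = np.zeros(len(consensus))
    for peak, count in peaks_with_counts:
        if count < 0:
            raise ValueError("peak counts must be >= 0")
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(peak.start, peak.end):
            out[hit.data] += count
    return out


def call_correlation_pairs(
    peaks_by_cell_type: Mapping[str, Sequence[Tuple[GenomicInterval, float]]],
    genes: Mapping[str, GeneAnnotation],
    config: Optional[CorrelationCallConfig] = None,
) -> CorrelationCallResult:
    """Call E/G pairs from pairwise accessibility correlation of peaks.

    Pipeline: merge every cell type's peaks into consensus peaks;
    aggregate each cell type's counts onto the consensus peaks; divide
    each cell type's counts by that cell type's total count in peaks;
    take log10(normalized + pseudocount); compute Pearson r for every
    same-chromosome consensus-peak pair closer than
    ``config.max_pair_distance``; keep pairs with r strictly above
    ``config.r_threshold``.  For every retained pair and every gene whose
    TSS one of the peaks overlaps, the call is (other peak, that gene),
    scored by r.  Undefined correlations never produce calls.
    """
    if config is None:
        config = CorrelationCallConfig()
    cell_types = sorted(peaks_by_cell_type)
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    consensus = merge_intervals(
        iv for ct in cell_types for iv, _ in peaks_by_cell_type[ct]
    )
    consensus = [
        GenomicInterval(cp.chrom, cp.start, cp.end, id=f"CP{idx:05d}")
        for idx, cp in enumerate(consensus)
    ]
    counts = np.column_stack(
        [_consensus_counts(consensus, peaks_by_cell_type[ct]) for ct in cell_types]
    ) if consensus else np.zeros((0, len(cell_types)))
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        bad = [ct for ct, t in zip(cell_types, totals) if t == 0]
        raise ValueError(f"cell types with zero total counts in peaks: {bad}")
    normalized = counts / totals
    logsig = np.log10(normalized + config.pseudocount)

    # genes whose TSS each consensus peak overlaps
    tss_hits: List[List[str]] = []
    for cp in consensus:
        hits = [
            gid
            for gid, g in genes.items()
            if g.chrom == cp.chrom
            and any(cp.start <= t < cp.end for t in g.tss_list)
        ]
        tss_hits.append(sorted(hits))

    calls: List[CandidatePair] = []
    n = len(consensus)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = consensus[i], consensus[j]
            gap = interval_gap(a, b)
            if gap >= config.max_pair_distance:
                continue
            if not tss_hits[i] and not tss_hits[j]:
                continue
            r, _, _ = _pearson_with_stats(logsig[i], logsig[j])
            if not (r > config.r_threshold):
                continue
            for anchor, other in ((i, j), (j, i)):
                for gid in tss_hits[anchor]:
                    calls.append(
                        CandidatePair(
                            element=consensus[other],
                            gene_id=gid,
                            scores={"correlation": r},
                        )
                    )
    matrix = SignalMatrix.from_arrays(
        [cp.id for cp in consensus], cell_types, normalized
    )
    return CorrelationCallResult(consensus, matrix, calls)
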