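"""Domain types, interval algebra, and file I/O for the E/G link pipeline.

Coordinates are 0-based half-open (BED convention) throughout.  A TSS is a
point, i.e. a 1 bp interval whose start is the TSS position.  Distances
between non-overlapping spans are positive gaps measured between nearest
covered bases; overlapping spans are at distance 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "SignalMatrix",
    "CandidatePair",
    "ReferenceSet",
    "PairFileError",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "interval_gap",
    "min_tss_distance",
    "intersect_with_catalog",
    "read_pair_file",
    "write_pair_file",
    "read_tss_bed",
]

#: Sentinel distance for element/gene pairs on different chromosomes: such a
#: pair can never be a candidate, so its distance is defined as +infinity.
INFINITE_DISTANCE = math.inf


class BedParseError(ValueError):
    """Raised when a BED record cannot be parsed; names the offending line."""


class PairFileError(ValueError):
    """Raised on malformed or internally inconsistent pair files."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a chromosome.

    Houses candidate regulatory elements (open-chromatin regions, cCREs)
    as well as generic intervals such as peaks and padded promoters.
    """

    chrom: str
    start: int
    end: int
    id: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two half-open spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneAnnotation:
    """A gene with one or more transcription start sites.

    ``expression`` optionally carries a per-cell-type nonnegative
    expression vector (ordered like the cell-type list of the matrices
    it is used alongside).
    """

    gene_id: str
    chrom: str
    tss_list: List[int]
    expression: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id}: tss_list must be non-empty")
        if any(t < 0 for t in self.tss_list):
            raise ValueError(f"gene {self.gene_id}: negative TSS position")
        if self.expression is not None:
            self.expression = np.asarray(self.expression, dtype=float)
            if np.any(self.expression < 0) or not np.all(
                np.isfinite(self.expression)
            ):
                raise ValueError(
                    f"gene {self.gene_id}: expression must be finite and >= 0"
                )


class SignalMatrix:
    """Nonnegative feature x cell-type value table.

    Thin wrapper around a :class:`pandas.DataFrame` (rows = features,
    columns = cell types) that enforces uniqueness of identifiers and
    nonnegative finite values.  Used for chromatin accessibility,
    expression, and H3K27ac signal across cell types.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate cell-type names")
        data = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(data)):
            raise ValueError("signal values must be finite")
        if np.any(data < 0):
            raise ValueError("signal values must be >= 0")
        self._df = values.astype(float)

    @classmethod
    def from_arrays(
        cls,
        feature_ids: Sequence[str],
        cell_types: Sequence[str],
        values: np.ndarray,
    ) -> "SignalMatrix":
        df = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=list(feature_ids),
            columns=list(cell_types),
        )
        return cls(df)

    @property
    def feature_ids(self) -> List[str]:
        return list(self._df.index)

    @property
    def cell_types(self) -> List[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def row(self, feature_id: str) -> np.ndarray:
        if feature_id not in self._df.index:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        return self._df.loc[feature_id].to_numpy()

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._df.index

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def write_tsv(self, path) -> None:
        """TSV with a header row of cell types; first column = feature id."""
        df = self._df.copy()
        df.index.name = "feature_id"
        with open(path, "w", newline="") as fh:
            df.to_csv(fh, sep="\t", lineterminator="\n")

    @classmethod
    def read_tsv(cls, path) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, SignalMatrix) and self._df.equals(other._df)


@dataclass
class CandidatePair:
    """A potential enhancer/gene link carrying named method scores.

    Score names in use: ``distance_score``, ``correlation``,
    ``correlation_p``, ``correlation_z``, ``average_rank_score``,
    ``abc_score``.  An undefined value (e.g. a correlation on a
    zero-variance vector) is stored as ``nan``.
    """

    element: GenomicInterval
    gene_id: str
    scores: Dict[str, float] = field(default_factory=dict)
    label: Optional[int] = None

    @property
    def element_id(self) -> str:
        if self.element.id is not None:
            return self.element.id
        return f"{self.element.chrom}:{self.element.start}-{self.element.end}"

    def set_score(self, name: str, value: float) -> None:
        v = float(value)
        if not (np.isfinite(v) or np.isnan(v)):
            raise ValueError(f"score {name}={value} must be finite or nan")
        self.scores[name] = v


class ReferenceSet:
    """Labeled (element id, gene id, 0/1) pairs: ground truth for evaluation."""

    def __init__(
        self,
        pairs: Optional[Mapping[Tuple[str, str], int]] = None,
        name: str = "",
    ):
        self.name = name
        self._labels: Dict[Tuple[str, str], int] = {}
        if pairs:
            for (eid, gid), label in pairs.items():
                self.add(eid, gid, label)

    def add(self, element_id: str, gene_id: str, label: int) -> None:
        if label not in (0, 1):
            raise PairFileError(f"label must be 0 or 1, got {label!r}")
        key = (element_id, gene_id)
        if key in self._labels and self._labels[key] != label:
            raise PairFileError(
                f"pair {key} appears with conflicting labels"
            )
        self._labels[key] = label

    def label(self, element_id: str, gene_id: str) -> Optional[int]:
        return self._labels.get((element_id, gene_id))

    def __contains__(self, key: Tuple[str, str]) -> bool:
        return key in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self):
        return iter(sorted(self._labels.items()))

    def items(self) -> List[Tuple[Tuple[str, str], int]]:
        return sorted(self._labels.items())

    @property
    def positives(self) -> Set[Tuple[str, str]]:
        return {k for k, v in self._labels.items() if v == 1}

    @property
    def negatives(self) -> Set[Tuple[str, str]]:
        return {k for k, v in self._labels.items() if v == 0}

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_negative(self) -> int:
        return len(self.negatives)

    def union(self, other: "ReferenceSet", name: str = "") -> "ReferenceSet":
        out = ReferenceSet(name=name or self.name)
        for key, label in list(self._labels.items()) + list(other._labels.items()):
            out.add(key[0], key[1], label)
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReferenceSet) and self._labels == other._labels
        )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> List[GenomicInterval]:
    """Sort and merge intervals; overlapping or bookended spans coalesce.

    Matches ``bedtools merge`` defaults: the output is sorted by
    (chrom, start), no two outputs overlap or abut, and the union of
    covered bases is preserved.  Ids and strands are dropped.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for iv in ordered:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start <= merged[-1].end
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between nearest covered bases of two intervals.

    0 when the intervals overlap; +inf when they lie on different
    chromosomes.  For disjoint same-chromosome spans the gap is the
    distance between the closest covered bases, e.g. [100,200) and
    [200,300) are 1 bp apart (bases 199 and 200).
    """
    if a.chrom != b.chrom:
        return INFINITE_DISTANCE
    if a.overlaps(b):
        return 0
    if a.end <= b.start:
        return b.start - (a.end - 1)
    return a.start - (b.end - 1)


def min_tss_distance(element: GenomicInterval, gene: GeneAnnotation) -> float:
    """Smallest distance between the element and any TSS of the gene.

    A TSS inside ``[start, end)`` is at distance 0; otherwise the gap to
    the nearest covered base (``start - tss`` upstream, ``tss - (end-1)``
    downstream).  Different chromosomes yield +inf: such a pair is not a
    candidate.
    """
    if element.chrom != gene.chrom:
        return INFINITE_DISTANCE
    best = INFINITE_DISTANCE
    for tss in gene.tss_list:
        if element.start <= tss < element.end:
            return 0
        d = element.start - tss if tss < element.start else tss - (element.end - 1)
        best = min(best, d)
    return best


def intersect_with_catalog(
    elements: Sequence[GenomicInterval],
    catalog: Sequence[GenomicInterval],
) -> List[Set[str]]:
    """Map each element to the ids of catalog intervals sharing >= 1 bp.

    Returns one id set per element, in input order; elements with no
    overlap map to the empty set.  Catalog ids must be unique.
    """
    ids = [c.id for c in catalog]
    if any(i is None for i in ids):
        raise ValueError("all catalog intervals need an id")
    if len(set(ids)) != len(ids):
        raise ValueError("catalog ids must be unique")
    trees: Dict[str, IntervalTree] = {}
    for c in catalog:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, c.id)
    out: List[Set[str]] = []
    for e in elements:
        tree = trees.get(e.chrom)
        if tree is None:
            out.append(set())
        else:
            out.append({hit.data for hit in tree.overlap(e.start, e.end)})
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(path) -> List[GenomicInterval]:
    """Read BED3/BED4/BED6 into intervals, preserving input order.

    The 4th column, when present, becomes the id; the 6th the strand.
    Malformed records raise :class:`BedParseError` naming the line.
    """
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else None
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, id=name, strand=strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w", newline="") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None or iv.strand is not None:
                cols.append(iv.id if iv.id is not None else ".")
            if iv.strand is not None:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def read_tss_bed(path) -> Dict[str, GeneAnnotation]:
    """Read a TSS BED (1 bp intervals named by gene id) into annotations.

    Multiple records sharing a gene id contribute multiple TSSs; all must
    lie on the same chromosome.
    """
    genes: Dict[str, GeneAnnotation] = {}
    for iv in read_bed(path):
        if iv.id is None:
            raise BedParseError(f"{path}: TSS records need a gene id column")
        if iv.id in genes:
            g = genes[iv.id]
            if g.chrom != iv.chrom:
                raise BedParseError(
                    f"{path}: gene {iv.id} has TSSs on multiple chromosomes"
                )
            g.tss_list.append(iv.start)
        else:
            genes[iv.id] = GeneAnnotation(iv.id, iv.chrom, [iv.start])
    for g in genes.values():
        g.tss_list.sort()
    return genes


def write_tss_bed(genes: Mapping[str, GeneAnnotation], path) -> None:
    with open(path, "w", newline="") as fh:
        for gid in sorted(genes):
            g = genes[gid]
            for tss in g.tss_list:
                fh.write(f"{g.chrom}\t{tss}\t{tss + 1}\t{gid}\n")


def read_pair_file(path, name: str = "") -> ReferenceSet:
    """Read a 3-column pair file (element id, gene id, 0/1 label).

    A 4th score column, when present, is ignored here (see
    :func:`read_scored_pair_file`).  Duplicate pairs with conflicting
    labels raise :class:`PairFileError`.
    """
    ref = ReferenceSet(name=name)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PairFileError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                label = int(fields[2])
            except ValueError as exc:
                raise PairFileError(
                    f"{path}:{lineno}: label must parse as 0/1"
                ) from exc
            try:
                ref.add(fields[0], fields[1], label)
            except PairFileError as exc:
                raise PairFileError(f"{path}:{lineno}: {exc}") from exc
    return ref


def write_pair_file(ref: ReferenceSet, path) -> None:
    """Write pairs sorted by (element id, gene id): byte-stable round trip."""
    with open(path, "w", newline="") as fh:
        for (eid, gid), label in ref.items():
            fh.write(f"{eid}\t{gid}\t{label}\n")


def read_scored_pair_file(path) -> List[Tuple[str, str, Optional[int], float]]:
    """Read a 4-column pair file: element id, gene id, label ('.'=unknown), score."""
    out: List[Tuple[str, str, Optional[int], float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PairFileError(
                    f"{path}:{lineno}: expected 4 tab-separated columns"
                )
            label = None if fields[2] == "." else int(fields[2])
            out.append((fields[0], fields[1], label, float(fields[3])))
    return out


def write_scored_pair_file(
    pairs: Sequence[CandidatePair], score_name: str, path
) -> None:
    """4-column pair file: element id, gene id, label ('.' if unknown), score."""
    rows = sorted(pairs, key=lambda p: (p.element_id, p.gene_id))
    with open(path, "w", newline="") as fh:
        for p in rows:
            label = "." if p.label is None else str(p.label)
            score = p.scores.get(score_name, float("nan"))
            fh.write(f"{p.element_id}\t{p.gene_id}\t{label}\t{score!r}\n")
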