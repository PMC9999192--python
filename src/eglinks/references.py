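"""Construction of ground-positive / ground-negative E/G reference sets.

Two families of rules are implemented:

* **BENGI-style negatives** — for each enhancer of a positive set, every
  annotated gene that is not its positive partner and lies within the
  95th percentile of the positive-set distances becomes a ground
  negative;
* **CRISPRi screen filtering (CRiFF-style)** — perturbation records are
  turned into labels: elements closer than 500 bp to any TSS are
  excluded as promoter-proximal, then a record is a ground positive when
  the perturbation is significant AND decreases expression, otherwise a
  ground negative.

Plus the whitelist used to force candidate regions: the merged union of
cCREs and TSSs padded by 250 bp on each side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .io_core import (
    GeneAnnotation,
    GenomicInterval,
    ReferenceSet,
    merge_intervals,
    min_tss_distance,
)

__all__ = [
    "ScreenRecord",
    "make_bengi_negatives",
    "filter_criff",
    "build_whitelist",
    "PROMOTER_EXCLUSION_BP",
    "DEFAULT_TSS_PAD_BP",
]

#: Records whose element lies closer than this to any TSS are dropped as
#: promoter-proximal before labeling.
PROMOTER_EXCLUSION_BP = 500

#: Padding applied to each side of a TSS when building the whitelist.
DEFAULT_TSS_PAD_BP = 250


@dataclass
class ScreenRecord:
    """One perturbation row of a CRISPRi-style genetic screen.

    ``expression_effect`` is the fractional change of the target gene's
    expression upon perturbation of the element; negative means a
    decrease (the signature of a true enhancer).
    """

    element: GenomicInterval
    gene_id: str
    significant: bool
    expression_effect: float

    @property
    def element_id(self) -> str:
        iv = self.element
        return iv.id if iv.id is not None else f"{iv.chrom}:{iv.start}-{iv.end}"


def make_bengi_negatives(
    positives: ReferenceSet,
    elements: Mapping[str, GenomicInterval],
    genes: Mapping[str, GeneAnnotation],
    percentile: float = 95.0,
) -> Tuple[ReferenceSet, float]:
    """Derive ground negatives from a positive set by the distance rule.

    The cutoff is the given percentile (linear interpolation between
    order statistics) of the multiset of element-to-gene distances over
    all positive pairs.  For each enhancer of the positive set, every
    annotated gene at distance <= cutoff that is not its positive
    partner becomes a label-0 pair.  Returns (negatives, cutoff); the
    negative set is disjoint from the positives by construction.
    """
    if len(positives) == 0:
        raise ValueError("positive set is empty")
    distances: List[float] = []
    for (eid, gid), label in positives.items():
        if label != 1:
            raise ValueError("positives must contain only label-1 pairs")
        if eid not in elements:
            raise KeyError(f"element {eid!r} not locatable")
        if gid not in genes:
            raise KeyError(f"gene {gid!r} not locatable")
        distances.append(min_tss_distance(elements[eid], genes[gid]))
    cutoff = float(np.percentile(distances, percentile))

    negatives = ReferenceSet(name=f"{positives.name}-negatives")
    pos_keys = positives.positives
    for eid in sorted({eid for eid, _ in pos_keys}):
        element = elements[eid]
        for gid in sorted(genes):
            if (eid, gid) in pos_keys:
                continue
            if min_tss_distance(element, genes[gid]) <= cutoff:
                negatives.add(eid, gid, 0)
    return negatives, cutoff


def filter_criff(
    records: Sequence[ScreenRecord],
    genes: Mapping[str, GeneAnnotation],
    exclusion_bp: float = PROMOTER_EXCLUSION_BP,
    name: str = "criff",
) -> Tuple[ReferenceSet, List[ScreenRecord]]:
    """Label screen records, excluding promoter-proximal elements.

    A record whose element lies strictly closer than ``exclusion_bp`` to
    any TSS of any gene is removed (promoter/promoter interaction).  Of
    the rest, significant perturbations that decrease expression are
    ground positives; everything else (not significant, or not a
    decrease) is a ground negative.  Returns (reference set, excluded
    records); the two partition the input.
    """
    reference = ReferenceSet(name=name)
    excluded: List[ScreenRecord] = []
    for rec in records:
        near_tss = any(
            min_tss_distance(rec.element, g) < exclusion_bp
            for g in genes.values()
        )
        if near_tss:
            excluded.append(rec)
            continue
        label = 1 if (rec.significant and rec.expression_effect < 0) else 0
        reference.add(rec.element_id, rec.gene_id, label)
    return reference, excluded


def build_whitelist(
    ccres: Iterable[GenomicInterval],
    genes: Mapping[str, GeneAnnotation],
    pad: int = DEFAULT_TSS_PAD_BP,
) -> List[GenomicInterval]:
    """Merged union of cCREs and TSSs extended by ``pad`` bp on each side.

    A TSS at position t contributes the interval [t - pad, t + pad + 1)
    (clipped at 0); the union of these with the cCREs is merged into
    disjoint spans.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    intervals = list(ccres)
    for g in genes.values():
        for t in g.tss_list:
            intervals.append(
                GenomicInterval(g.chrom, max(0, t - pad), t + pad + 1)
            )
    return merge_intervals(intervals)


def read_screen_records(path) -> List[ScreenRecord]:
    """Read screen records from TSV: chrom, start, end, gene_id,
    significant{0,1}, effect."""
    out: List[ScreenRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated columns"
                )
            out.append(
                ScreenRecord(
                    element=GenomicInterval(
                        fields[0], int(fields[1]), int(fields[2])
                    ),
                    gene_id=fields[3],
                    significant=bool(int(fields[4])),
                    expression_effect=float(fields[5]),
                )
            )
    return out
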