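import numpy as np
import pytest

from eglinks import GeneAnnotation, GenomicInterval


@pytest.fixture
def simple_genes():
    """Three genes on chr1 with known TSS positions."""
    return {
        "G1": GeneAnnotation("G1", "chr1", [10_000]),
        "G2": GeneAnnotation("G2", "chr1", [50_000]),
        "G3": GeneAnnotation("G3", "chr1", [200_000]),
    }


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=500):
    """Random valid intervals for oracle comparisons."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(
                str(rng.choice(list(chroms))), start, start + length, id=f"I{i}"
            )
        )
    return out


def occupancy_union(intervals):
    """Brute-force per-base occupancy: the set of (chrom, base) covered."""
    covered = set()
    for iv in intervals:
        for b in range(iv.start, iv.end):
            covered.add((iv.chrom, b))
    return covered


def segments_from_occupancy(covered):
    """Re-segment a per-base occupancy set into maximal disjoint runs."""
    by_chrom = {}
    for chrom, b in covered:
        by_chrom.setdefault(chrom, set()).add(b)
    segments = []
    for chrom in sorted(by_chrom):
        bases = sorted(by_chrom[chrom])
        start = prev = bases[0]
        for b in bases[1:]:
            if b != prev + 1:
                segments.append((chrom, start, prev + 1))
                start = b
            prev = b
        segments.append((chrom, start, prev + 1))
    return segments
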