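#!/usr/bin/env python
"""Build the three flavors of reference material from the synthetic bundle.

1. BENGI-style ground negatives: for each enhancer of the positive set,
   every gene within the 95th percentile of the positive distances that
   is not its partner.
2. A CRISPRi-screen style reference: perturbation records synthesized
   from the truth (wired pairs show a significant expression decrease),
   then filtered — promoter-proximal elements dropped, significant
   decreases labeled positive.
3. The candidate whitelist: merged union of elements and TSSs padded by
   250 bp.

Outputs land under results/references/.
"""

import argparse
from pathlib import Path

import numpy as np

from eglinks import (
    build_whitelist,
    filter_criff,
    make_bengi_negatives,
    read_bed,
    read_pair_file,
    read_tss_bed,
    write_bed,
    write_pair_file,
)
from eglinks.io_core import ReferenceSet
from eglinks.references import ScreenRecord


def synthesize_screen(truth, elements, rng):
    """Perturbation outcomes consistent with the wiring: knocking down a
    true enhancer significantly decreases its target's expression."""
    records = []
    for (eid, gid), label in truth.items():
        if label == 1:
            significant = rng.random() < 0.9
            effect = -float(rng.uniform(0.15, 0.6))
        else:
            significant = rng.random() < 0.1
            effect = float(rng.normal(0, 0.05))
        records.append(ScreenRecord(elements[eid], gid, significant, effect))
    return records


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle-dir", type=Path,
                        default=Path("results/synthetic"))
    parser.add_argument("--out-dir", type=Path,
                        default=Path("results/references"))
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    genes = read_tss_bed(args.bundle_dir / "tss.bed")
    elements = {e.id: e for e in read_bed(args.bundle_dir / "elements.bed")}
    truth = read_pair_file(args.bundle_dir / "truth.pairs")

    positives = ReferenceSet(name="synthetic-positives")
    for (eid, gid), label in truth.items():
        if label == 1:
            positives.add(eid, gid, 1)

    negatives, cutoff = make_bengi_negatives(positives, elements, genes)
    write_pair_file(negatives, args.out_dir / "bengi_negatives.pairs")
    write_pair_file(
        positives.union(negatives, name="bengi-style"),
        args.out_dir / "bengi_reference.pairs",
    )
    print(f"BENGI rule: {len(positives)} positives -> {len(negatives)} "
          f"negatives (95th-percentile distance cutoff {cutoff:,.0f} bp)")

    rng = np.random.default_rng(args.seed)
    records = synthesize_screen(truth, elements, rng)
    screen_ref, excluded = filter_criff(records, genes)
    write_pair_file(screen_ref, args.out_dir / "screen_reference.pairs")
    print(f"screen filter: {len(records)} records -> "
          f"{screen_ref.n_positive} positives, {screen_ref.n_negative} "
          f"negatives, {len(excluded)} promoter-proximal excluded")

    whitelist = build_whitelist(elements.values(), genes)
    write_bed(whitelist, args.out_dir / "whitelist.bed")
    covered = sum(iv.length for iv in whitelist)
    print(f"whitelist: {len(whitelist)} merged intervals, "
          f"{covered:,} bp covered")


if __name__ == "__main__":
    main()
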