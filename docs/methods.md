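# Methods

## Coordinate and distance conventions

All intervals are 0-based half-open (BED convention); a TSS is the 1 bp
interval `[t, t+1)`. The distance between disjoint spans is the gap
between their nearest covered bases, so `[100,200)` and `[200,300)` are
1 bp apart and an element containing a TSS is at distance 0. The
element-to-gene distance is the minimum of this gap over the gene's
TSSs; elements and genes on different chromosomes are at +inf and never
form candidates. Strand is carried through I/O but ignored by all
scoring — none of the implemented methods is strand-aware.

Inverse-distance quantities (the distance score and the distance-decay
contact) apply a 1 bp floor before inversion: `1 / max(d, 1)`. This
keeps scores finite for TSS-overlapping elements and preserves the
ordering of all other pairs.

## Scoring methods

**Distance.** `score = 1 / max(d(E,G), 1)`. Strictly decreasing in the
distance; the simplest baseline.

**Sheffield correlation.** Pearson *r* between `log10(accessibility at
E + c)` and `log10(expression of G + c)` across an identical ordered
cell-type list (≥ 3 cell types required), with pseudocount `c = 1` by
default — the standard convention for count data, configurable down to
effectively zero for depth-normalized inputs. Zero-variance vectors
yield an undefined-correlation sentinel (`nan`) that sorts below every
defined value wherever correlations are ranked. A two-sided p-value
(t approximation on n−2 df) and a Fisher Z score (`atanh(r)·sqrt(n−3)`)
are attached for inspection, but only *r* drives ranking.

**Average-Rank.** Each pair is ranked separately by distance score and
by correlation (rank 1 = best, descending order, ties mid-ranked); the
score is the inverse of the mean of the two ranks. Because it is
rank-based it is invariant under any strictly monotone transform of
either input. Ranks are computed within the supplied candidate set;
output files are sorted by (element id, gene id) so results are
deterministic under input permutation.

**ABC.** Activity `A(E) = sqrt((acc + c0)(h3k27ac + c0))` with `c0 = 0`
by default (a zero count annihilates activity, as for raw read counts);
contact `C(E,G)` either looked up in a normalized contact table
(absent pair → 0) or `1/max(d, floor)` under the distance-decay
(fractal-globule) model. The score of `(E,G)` is `A·C` normalized by
the sum of `A·C` over all candidate elements whose distance to the gene
is at most half the 5 Mb window (i.e. a window centered on the TSS).
In-window scores therefore sum to exactly 1 whenever any product is
positive; an all-zero denominator yields all-zero scores rather than an
error. Gene expression filtering accepts either measured expression or
promoter activity (same geometric-mean form) as a proxy.

**Correlation caller.** Per-cell-type peak sets are merged into
consensus peaks (sort + merge, bookended intervals coalesce, matching
`bedtools merge` defaults); each cell type's per-peak counts are summed
onto overlapping consensus peaks and divided by that cell type's total
count in peaks (sequencing-depth normalization). Pairwise Pearson *r*
is computed on `log10(fraction + pseudocount)` for same-chromosome
pairs closer than 500 kb; pairs with `r > 0.7` where one peak covers a
gene TSS yield the call (other peak, that gene). If both peaks sit on
TSSs, a call is emitted in each direction. The caller's default
pseudocount is `1e-4`, not 1: normalized signals are fractions of a
cell type's reads (typically 1e-4–1e-2 here), and a pseudocount of 1
would flatten the log scale entirely. It is exposed in the
configuration for sensitivity analysis.

## Reference-set construction

**Distance-percentile negatives.** The cutoff is the 95th percentile of
the positive pairs' element-to-gene distances, computed by linear
interpolation between order statistics (numpy's default, type 7); the
convention is recorded here because alternative percentile definitions
shift the cutoff on small sets. Every (positive-set enhancer, annotated
gene) pair at distance ≤ cutoff that is not itself positive becomes a
ground negative; the output is disjoint from the positives by
construction. The percentile is computed per positive set, and the gene
anchor is the same nearest-TSS distance used by the distance method.

**Screen filtering.** Records whose element lies strictly closer than
500 bp to any TSS are removed as promoter-proximal (same gap
convention as above). Of the rest, label 1 requires significance *and*
a negative expression effect (perturbing a true enhancer decreases its
target); everything else — not significant, or an expression increase —
is label 0. Positives, negatives and excluded records partition the
input.

**Whitelist.** Merged union of the element catalog and TSSs padded by
250 bp on each side (`[t−250, t+251)`, clipped at zero). Increasing the
pad can only grow the covered bases.

## Evaluation

PR curves sweep the distinct score values in descending order; tied
scores enter as one block, so a curve never depends on input order.
AUPR uses step-wise integration — each threshold contributes (recall
increment) × (precision there) — which equals average precision;
trapezoidal integration is deliberately avoided because it
overestimates PR areas. With continuous scores this reduces to the sum
over ranked positives of precision-at-that-rank divided by the number
of positives, which the tests use as an independent oracle (alongside
scikit-learn's `average_precision_score`).

Thresholded (binary) predictions cannot be swept, so they are reduced
to a single point: precision = TP / (positive predictions found in the
reference), pessimistic recall = TP / (all reference positives), and
optimistic recall = TP / (reference positives inside the predictor's
own pair universe). Reported percentages follow the conventional table
formatting (precision to 1 decimal, recalls to 2); unrounded values are
kept alongside. Zero denominators produce a `nan` sentinel rather than
an error. Coordinate-space predictions are resolved to (catalog id,
gene id) pairs by ≥1 bp interval overlap against the element catalog
and by TSS containment for promoters; distinct resolved pairs are
counted, so duplicated predictions do not inflate any count.

## Synthetic regulatory genome

The generator emulates the *structure* of the real inputs — per-cell-
type accessibility and expression count matrices over a shared cell
type panel, H3K27ac counts, a contact table, labeled pairs — not their
genomic realism. The model:

- `n_genes` single-TSS genes and `n_elements` 300 bp elements placed
  uniformly on `n_chromosomes` chromosomes, with every element at least
  1 kb from every TSS (so no candidate is promoter-proximal);
- each (element, gene) pair within `max_wiring_distance` (default
  100 kb) is a true link with probability `wiring_prob` (default 0.3);
  the truth set labels these 1 and every other within-range pair 0;
- per cell type, each element has a latent activation `a ~ N(0,1)`;
  log accessibility = base + `signal_effect`·a + noise; a gene's log
  expression couples to the *mean* latent of its true enhancers; wired
  elements also get a constant baseline log-activity boost
  (`activity_boost`, default 3 ≈ 20× counts) — true enhancers are more
  accessible and more acetylated than bystander open chromatin;
- H3K27ac follows accessibility with lognormal jitter (sd 0.3);
  contacts are `1/max(d, 1 kb)` with lognormal jitter (sd 0.5),
  tabulated out to 1 Mb;
- matrices are emitted as rounded integer counts to match read-count
  semantics; all randomness flows from one seed through per-output
  sub-streams, so bundles are byte-reproducible and adding an output
  stream cannot perturb existing ones.

Defaults (2 × 10 Mb, 60 genes, 400 elements, 30 cell types,
`signal_effect` 2, `noise_sd` 0.5) give ≈ 240 candidate pairs at ≈ 0.3
prevalence and keep a full pipeline run under a minute. These defaults
define the recovery regime the benchmark is built around: the
correlation signal (`signal_effect` 2 against noise sd 0.5) makes
Sheffield nearly saturating, and the activity boost of 3 log-units
separates ABC well above prevalence. A boost much below 2 would push
ABC toward its structural ceiling too slowly to distinguish from
chance: elements wired to a *neighboring* gene carry the same boost, so
some negatives are intrinsically confusable — a deliberate, realistic
property of the simulation.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: realistic peak shapes, read
sampling noise, shared batch/depth structure across cell types,
multi-TSS isoform structure, enhancer–enhancer cooperation, and the
enrichment of 3D contact at true loops (contacts here are pure distance
decay with noise, carrying *no* wiring information; ABC's recovery
comes entirely from activity). Because true and false pairs share the
same distance range, the inverse-distance baseline hovers at
prevalence under the default flat wiring; a `proximity_bias` option
concentrates wiring near TSSs for experiments where distance should be
informative.

For truth recovery the per-pair ABC score pools activity across cell
types by geometric mean before the per-gene normalization. The ABC
score is defined within one cell type; a single-cell-type run carries
the full per-cell-type activation noise (`signal_effect`·a, the same
magnitude as the boost), whereas the geometric pool estimates the
element's baseline activity, which is the quantity the generator makes
discriminative. This choice is part of the benchmark harness, not of
the ABC definition, which `score_abc` implements per cell type.

## Numerical choices and degenerate inputs

- Undefined correlations (`nan`) are excluded from correlation calls,
  rank last in Average-Rank, and are floored below the minimum defined
  score before PR sweeps.
- Pearson *r* is clipped to [−1, 1] before the p/Z transforms to guard
  against floating-point overshoot on exact linear relations.
- Empty interval lists merge to empty; an empty candidate set scores to
  an empty output; a PR sweep without positives is an error (recall is
  undefined), as is a reference set that is empty or internally
  label-inconsistent.
- Pair files are written sorted by (element id, gene id), so
  write → read → write round trips are byte-stable.

## Problem sizes

Tests and the acceptance script run the synthetic pipeline at the
default bundle size (≈ 240 pairs, 30 cell types) with 20 seeded
replicates for the recovery medians, 200 random score sets (≤ 1,000
pairs) for the AUPR oracle check, and 100 random instances for ABC
conservation — sizes chosen so the whole suite completes in well under
a minute while keeping Monte-Carlo noise far from the asserted margins.
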