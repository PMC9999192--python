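"""The five scoring procedures against hand-computed and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from eglinks import (
    ABCElement,
    CandidatePair,
    ContactModel,
    CorrelationCallConfig,
    GeneAnnotation,
    GenomicInterval,
    SignalMatrix,
    abc_activity,
    abc_contact,
    call_correlation_pairs,
    filter_expressed_genes,
    min_tss_distance,
    score_abc,
    score_average_rank,
    score_distance,
    score_sheffield,
)
from eglinks.io_core import interval_gap


def make_pair(element_id, gene_id, chrom="chr1", start=0, end=100, **scores):
    p = CandidatePair(
        element=GenomicInterval(chrom, start, end, id=element_id),
        gene_id=gene_id,
    )
    for k, v in scores.items():
        p.scores[k] = v
    return p


class TestScoreDistance:
    def test_inverse_with_floor(self):
        genes = {
            "G1": GeneAnnotation("G1", "chr1", [599]),   # gap 500 from [0,100)
            "G2": GeneAnnotation("G2", "chr1", [50]),    # overlapping TSS
        }
        pairs = [make_pair("E1", "G1"), make_pair("E2", "G2")]
        score_distance(pairs, genes)
        assert pairs[0].scores["distance_score"] == pytest.approx(1 / 500)
        assert pairs[1].scores["distance_score"] == 1.0

    def test_strictly_decreasing_in_distance(self):
        genes = {
            f"G{d}": GeneAnnotation(f"G{d}", "chr1", [99 + d])
            for d in (10, 100, 1000)
        }
        pairs = [make_pair(f"E{d}", f"G{d}") for d in (10, 100, 1000)]
        score_distance(pairs, genes)
        s = [p.scores["distance_score"] for p in pairs]
        assert s == [0.1, 0.01, 0.001]

    def test_unknown_gene_named_in_error(self):
        with pytest.raises(KeyError, match="GX"):
            score_distance([make_pair("E1", "GX")], {})


def matrix(rows, cell_types=None):
    ids = sorted(rows)
    cts = cell_types or [f"ct{i}" for i in range(len(next(iter(rows.values()))))]
    return SignalMatrix.from_arrays(ids, cts, [rows[i] for i in ids])


class TestScoreSheffield:
    def test_exact_log_linear_relation(self):
        acc = matrix({"E1": [1, 10, 100, 1000]})
        expr = matrix({"G1": [2, 20, 200, 2000]})
        (pair,) = score_sheffield(
            [make_pair("E1", "G1")], acc, expr, pseudocount=1e-12
        )
        assert pair.scores["correlation"] == pytest.approx(1.0)

    def test_zero_variance_gives_nan_sentinel(self):
        acc = matrix({"E1": [1, 2, 3, 4]})
        expr = matrix({"G1": [5, 5, 5, 5]})
        (pair,) = score_sheffield([make_pair("E1", "G1")], acc, expr)
        assert math.isnan(pair.scores["correlation"])

    def test_hand_computed_pearson_on_logged_vectors(self):
        # Pearson of log10(x+1) for x=(3,1,4,1,5) vs y=(9,2,6,5,3),
        # frozen from the textbook covariance/variance formula.
        acc = matrix({"E1": [3, 1, 4, 1, 5]})
        expr = matrix({"G1": [9, 2, 6, 5, 3]})
        (pair,) = score_sheffield([make_pair("E1", "G1")], acc, expr, pseudocount=1)
        assert pair.scores["correlation"] == pytest.approx(
            0.292793790295453, abs=1e-12
        )
        assert 0 < pair.scores["correlation_p"] <= 1
        assert np.isfinite(pair.scores["correlation_z"])

    def test_mismatched_cell_types_rejected(self):
        acc = matrix({"E1": [1, 2, 3]}, ["a", "b", "c"])
        expr = matrix({"G1": [1, 2, 3]}, ["a", "b", "d"])
        with pytest.raises(ValueError, match="cell types"):
            score_sheffield([make_pair("E1", "G1")], acc, expr)

    def test_global_rescaling_invariance_at_zero_pseudocount(self):
        # rescaling a whole signal (e.g. sequencing depth) only shifts its
        # log vector, leaving Pearson r unchanged when pseudocount ~ 0
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 100, size=6)
        y = rng.uniform(1, 100, size=6)
        r0 = score_sheffield(
            [make_pair("E1", "G1")], matrix({"E1": x}), matrix({"G1": y}),
            pseudocount=1e-300,
        )[0].scores["correlation"]
        r1 = score_sheffield(
            [make_pair("E1", "G1")],
            matrix({"E1": x * 50.0}), matrix({"G1": y * 3.0}),
            pseudocount=1e-300,
        )[0].scores["correlation"]
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_global_rescaling_invariance_asymptotic_with_pseudocount(self):
        # with pseudocount 1 the log shift is inexact but the deviation
        # vanishes as counts grow
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, size=6)
        y = rng.uniform(1, 10, size=6)
        deviations = []
        for mag in (1e2, 1e5, 1e8):
            r0 = score_sheffield(
                [make_pair("E1", "G1")],
                matrix({"E1": x * mag}), matrix({"G1": y * mag}),
                pseudocount=1,
            )[0].scores["correlation"]
            r1 = score_sheffield(
                [make_pair("E1", "G1")],
                matrix({"E1": x * 7.0 * mag}), matrix({"G1": y * mag}),
                pseudocount=1,
            )[0].scores["correlation"]
            deviations.append(abs(r1 - r0))
        assert deviations[-1] < 1e-9 and deviations[-1] <= deviations[0]


class TestScoreAverageRank:
    def test_forced_by_formula(self):
        pairs = [
            make_pair("E1", "G1", distance_score=0.5, correlation=0.9),
            make_pair("E2", "G2", distance_score=0.1, correlation=0.2),
        ]
        score_average_rank(pairs)
        assert pairs[0].scores["average_rank_score"] == 1.0
        assert pairs[1].scores["average_rank_score"] == 0.5

    def test_crossed_ranks_are_symmetric(self):
        pairs = [
            make_pair("E1", "G1", distance_score=0.9, correlation=0.1),
            make_pair("E2", "G2", distance_score=0.5, correlation=0.5),
            make_pair("E3", "G3", distance_score=0.1, correlation=0.9),
        ]
        score_average_rank(pairs)
        assert (
            pairs[0].scores["average_rank_score"]
            == pairs[2].scores["average_rank_score"]
            == 0.5
        )

    def test_undefined_correlation_ranks_last(self):
        pairs = [
            make_pair("E1", "G1", distance_score=0.9, correlation=float("nan")),
            make_pair("E2", "G2", distance_score=0.5, correlation=0.5),
        ]
        score_average_rank(pairs)
        assert pairs[0].scores["correlation_rank"] == 2

    def test_ordering_matches_brute_force_mean_rank(self):
        rng = np.random.default_rng(5)
        pairs = [
            make_pair(f"E{i}", f"G{i}",
                      distance_score=float(rng.random()),
                      correlation=float(rng.uniform(-1, 1)))
            for i in range(20)
        ]
        score_average_rank(pairs)
        # brute force: rank by sorting each score descending
        def brute_ranks(key):
            order = sorted(pairs, key=lambda p: -p.scores[key])
            return {id(p): i + 1 for i, p in enumerate(order)}
        rd, rc = brute_ranks("distance_score"), brute_ranks("correlation")
        brute_order = sorted(pairs, key=lambda p: rd[id(p)] + rc[id(p)])
        got_order = sorted(
            pairs, key=lambda p: -p.scores["average_rank_score"]
        )
        assert [id(p) for p in got_order] == [id(p) for p in brute_order]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        base = [
            make_pair(f"E{i}", f"G{i}",
                      distance_score=float(rng.random()),
                      correlation=float(rng.uniform(-1, 1)))
            for i in range(15)
        ]
        transformed = [
            make_pair(p.element_id, p.gene_id,
                      distance_score=math.exp(3 * p.scores["distance_score"]),
                      correlation=math.atan(5 * p.scores["correlation"]))
            for p in base
        ]
        score_average_rank(base)
        score_average_rank(transformed)
        for a, b in zip(base, transformed):
            assert a.scores["average_rank_score"] == pytest.approx(
                b.scores["average_rank_score"]
            )

    def test_empty_input(self):
        assert score_average_rank([]) == []


class TestABC:
    def test_activity_geometric_mean(self):
        e = ABCElement(GenomicInterval("chr1", 0, 100, id="E"), 4, 16)
        assert abc_activity(e) == 8
        e0 = ABCElement(GenomicInterval("chr1", 0, 100, id="E"), 0, 100)
        assert abc_activity(e0) == 0
        e1 = ABCElement(GenomicInterval("chr1", 0, 100, id="E"), 7, 13)
        assert abc_activity(e1, pseudocount=1) == pytest.approx(math.sqrt(8 * 14))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ABCElement(GenomicInterval("chr1", 0, 100), -1, 5)

    def test_contact_decay_and_table(self):
        gene = GeneAnnotation("G", "chr1", [1100])
        e = ABCElement(GenomicInterval("chr1", 0, 100, id="E"), 1, 1)
        assert abc_contact(e, gene, ContactModel()) == pytest.approx(1 / 1001)
        table = ContactModel(mode="table", table={("E", "G"): 7.5})
        assert abc_contact(e, gene, table) == 7.5
        assert abc_contact(e, gene, ContactModel(mode="table", table={})) == 0.0

    def test_single_element_self_normalizes(self):
        gene = GeneAnnotation("G", "chr1", [5_000])
        e = ABCElement(GenomicInterval("chr1", 0, 100, id="E"), 10, 10)
        assert score_abc([e], gene, ContactModel()) == {"E": 1.0}

    def test_equal_products_split_evenly(self):
        gene = GeneAnnotation("G", "chr1", [50_000])
        els = [
            ABCElement(GenomicInterval("chr1", 10_000, 10_100, id="A"), 4, 4),
            ABCElement(GenomicInterval("chr1", 89_901, 90_001, id="B"), 4, 4),
        ]
        scores = score_abc(els, gene, ContactModel())
        assert scores["A"] == pytest.approx(0.5)
        assert scores["B"] == pytest.approx(0.5)

    def test_hand_normalized_products(self):
        gene = GeneAnnotation("G", "chr1", [0])
        activities = [4, 9, 16, 25, 36]
        contacts = {}
        els = []
        for i, a in enumerate(activities):
            eid = f"E{i}"
            els.append(
                ABCElement(
                    GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 50,
                                    id=eid),
                    a, a,
                )
            )
            contacts[(eid, "G")] = float(i + 1)
        model = ContactModel(mode="table", table=contacts)
        scores = score_abc(els, gene, model)
        products = [a * (i + 1) for i, a in enumerate(activities)]
        total = sum(products)
        for i, prod in enumerate(products):
            assert scores[f"E{i}"] == pytest.approx(prod / total)

    def test_window_excludes_far_elements(self):
        gene = GeneAnnotation("G", "chr1", [0])
        near = ABCElement(GenomicInterval("chr1", 1000, 1100, id="N"), 5, 5)
        far = ABCElement(
            GenomicInterval("chr1", 4_000_000, 4_000_100, id="F"), 5, 5
        )
        scores = score_abc([near, far], gene, ContactModel(), window=5_000_000)
        assert set(scores) == {"N"}

    def test_all_zero_denominator_gives_zeros(self):
        gene = GeneAnnotation("G", "chr1", [0])
        e = ABCElement(GenomicInterval("chr1", 1000, 1100, id="E"), 0, 5)
        assert score_abc([e], gene, ContactModel()) == {"E": 0.0}

    def test_invalid_window_rejected(self):
        gene = GeneAnnotation("G", "chr1", [0])
        with pytest.raises(ValueError):
            score_abc([], gene, ContactModel(), window=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        gene = GeneAnnotation("G", "chr1", [500_000])
        els = []
        table = {}
        for i in range(30):
            start = int(rng.integers(0, 1_000_000))
            eid = f"E{i}"
            els.append(
                ABCElement(
                    GenomicInterval("chr1", start, start + 100, id=eid),
                    float(rng.integers(0, 50)), float(rng.integers(0, 50)),
                )
            )
            if rng.random() < 0.8:
                table[(eid, "G")] = float(rng.uniform(0, 5))
        model = ContactModel(mode="table", table=table)
        scores = score_abc(els, gene, model)
        products = [
            abc_activity(e) * abc_contact(e, gene, model) for e in els
        ]
        if any(p > 0 for p in products):
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-12)
        else:
            assert all(v == 0 for v in scores.values())


class TestFilterExpressedGenes:
    def test_threshold_zero_keeps_all(self, simple_genes):
        expr = {g: 0.0 for g in simple_genes}
        assert filter_expressed_genes(simple_genes, 0, expression=expr) == simple_genes

    def test_count_by_comparison(self, simple_genes):
        expr = dict(zip(sorted(simple_genes), [0.0, 5.0, 30.0]))
        kept = filter_expressed_genes(simple_genes, 20, expression=expr)
        assert list(kept) == ["G3"]

    def test_promoter_activity_proxy_matches_direct_threshold(self):
        rng = np.random.default_rng(2)
        genes = {
            f"G{i}": GeneAnnotation(f"G{i}", "chr1", [i * 1000]) for i in range(10)
        }
        activity = {g: float(rng.uniform(0, 50)) for g in genes}
        kept = filter_expressed_genes(genes, 25, promoter_activity=activity)
        assert set(kept) == {g for g, a in activity.items() if a >= 25}

    def test_gene_without_signal_is_error(self, simple_genes):
        with pytest.raises(KeyError, match="G2"):
            filter_expressed_genes(simple_genes, 0, expression={"G1": 1.0, "G3": 1.0})


def brute_force_calls(peaks_by_ct, genes, config):
    """All-pairs recomputation of the correlation caller's pipeline."""
    from eglinks import merge_intervals

    cts = sorted(peaks_by_ct)
    consensus = merge_intervals(
        iv for ct in cts for iv, _ in peaks_by_ct[ct]
    )
    counts = np.zeros((len(consensus), len(cts)))
    for j, ct in enumerate(cts):
        for peak, count in peaks_by_ct[ct]:
            for i, cp in enumerate(consensus):
                if cp.overlaps(peak):
                    counts[i, j] += count
    norm = counts / counts.sum(axis=0)
    logsig = np.log10(norm + config.pseudocount)
    calls = set()
    for i, j in itertools.combinations(range(len(consensus)), 2):
        a, b = consensus[i], consensus[j]
        if interval_gap(a, b) >= config.max_pair_distance:
            continue
        if np.ptp(logsig[i]) == 0 or np.ptp(logsig[j]) == 0:
            continue
        r = np.corrcoef(logsig[i], logsig[j])[0, 1]
        if not r > config.r_threshold:
            continue
        for anchor, other in ((a, b), (b, a)):
            for gid, g in genes.items():
                if g.chrom == anchor.chrom and any(
                    anchor.start <= t < anchor.end for t in g.tss_list
                ):
                    calls.add(((other.chrom, other.start, other.end), gid))
    return calls


class TestCorrelationCaller:
    def two_peak_setup(self, second_start):
        # two peaks with identical count profiles plus a distant,
        # non-proportional peak so normalization keeps their variance
        background = [7.0, 3.0, 11.0, 5.0]
        peaks = {
            f"ct{j}": [
                (GenomicInterval("chr1", 1000, 1200), float(10 * (j + 1))),
                (GenomicInterval("chr1", second_start, second_start + 200),
                 float(10 * (j + 1))),
                (GenomicInterval("chr1", 900_000, 900_200), background[j]),
            ]
            for j in range(4)
        }
        genes = {"G1": GeneAnnotation("G1", "chr1", [1100])}
        return peaks, genes

    def test_perfect_correlation_on_tss_yields_one_call(self):
        peaks, genes = self.two_peak_setup(50_000)
        result = call_correlation_pairs(peaks, genes)
        assert len(result.calls) == 1
        call = result.calls[0]
        assert call.gene_id == "G1"
        assert call.element.start == 50_000
        assert call.scores["correlation"] == pytest.approx(1.0)

    def test_distance_cutoff_blocks_call(self):
        peaks, genes = self.two_peak_setup(700_000)
        result = call_correlation_pairs(peaks, genes)
        assert result.calls == []

    def test_zero_total_counts_is_error(self):
        peaks = {
            "ct0": [(GenomicInterval("chr1", 0, 100), 0.0)],
            "ct1": [(GenomicInterval("chr1", 0, 100), 1.0)],
        }
        with pytest.raises(ValueError, match="zero total"):
            call_correlation_pairs(peaks, {})

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = {
            f"G{i}": GeneAnnotation(f"G{i}", "chr1", [int(rng.integers(0, 800_000))])
            for i in range(5)
        }
        peaks = {}
        for j in range(10):
            rows = []
            for i in range(30):
                start = int(rng.integers(0, 800_000))
                rows.append(
                    (GenomicInterval("chr1", start, start + 300),
                     float(rng.integers(1, 200)))
                )
            peaks[f"ct{j}"] = rows
        config = CorrelationCallConfig()
        result = call_correlation_pairs(peaks, genes, config)
        got = {
            ((c.element.chrom, c.element.start, c.element.end), c.gene_id)
            for c in result.calls
        }
        assert got == brute_force_calls(peaks, genes, config)

    def test_exhaustive_limit_returns_every_tss_anchored_pair(self):
        rng = np.random.default_rng(9)
        genes = {"G1": GeneAnnotation("G1", "chr1", [10_050])}
        peaks = {
            f"ct{j}": [
                (GenomicInterval("chr1", 1000 * i + 10_000, 1000 * i + 10_100),
                 float(rng.integers(1, 100)))
                for i in range(6)
            ]
            for j in range(5)
        }
        config = CorrelationCallConfig(
            max_pair_distance=math.inf, r_threshold=-1.0
        )
        result = call_correlation_pairs(peaks, genes, config)
        # the TSS peak pairs with each of the 5 other peaks
        assert len(result.calls) == 5
        assert all(c.gene_id == "G1" for c in result.calls)
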