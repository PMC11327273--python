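"""Cluster characterization: complexity, peak statistics, consensus, group tests."""

from __future__ import annotations

import math

import numpy as np
import pytest

from smrclust.metrics import (
    characterize,
    compare_properties,
    complexity,
    consensus,
    peak_stats,
)

from conftest import make_cluster, make_read, make_stack, make_ugr


class TestComplexity:
    def test_single_start_scores_zero(self):
        assert complexity(make_cluster(make_stack(100, 100))) == 0.0

    def test_uniform_length_one_tiling_scores_one(self):
        reads = [
            make_read(100 + i, 101 + i, read_id=f"b{i}", seq="A") for i in range(64)
        ]
        assert complexity(make_cluster(reads)) == 1.0

    def test_two_equal_starts_in_span_four(self):
        reads = [
            make_read(100, 101, seq="A", read_id="a"),
            make_read(103, 104, seq="A", read_id="b"),
        ]
        assert complexity(make_cluster(reads)) == pytest.approx(
            math.log(2) / math.log(4)
        )

    def test_bounded_and_spreading_monotone(self, rng):
        """Moving mass from the modal start to an empty start never decreases it."""
        for _ in range(50):
            n_starts = int(rng.integers(1, 10))
            starts = sorted(rng.choice(np.arange(100, 160), n_starts, replace=False))
            reads = []
            for i, s in enumerate(starts):
                for j in range(int(rng.integers(1, 8))):
                    reads.append(make_read(int(s), int(s) + 30, read_id=f"r{i}_{j}"))
            c = make_cluster(reads)
            val = complexity(c)
            assert 0.0 <= val <= 1.0
            # spread: move one read from the modal start to a fresh start
            counts = {}
            for r in reads:
                counts[r.alignment.start] = counts.get(r.alignment.start, 0) + 1
            modal = max(counts, key=lambda s: counts[s])
            fresh = modal + 1 if modal + 1 not in counts else None
            if fresh is not None and counts[modal] > 1 and fresh + 30 <= c.end:
                moved = [r for r in reads if r.alignment.start != modal]
                keep = [r for r in reads if r.alignment.start == modal][:-1]
                spread = moved + keep + [make_read(fresh, fresh + 30, read_id="mv")]
                assert complexity(make_cluster(spread)) >= val - 1e-12

    def test_weight_rescaling_invariance(self):
        reads = make_stack(100, 10) + make_stack(140, 5)
        scaled = [make_read(r.alignment.start, r.alignment.end, weight=0.37,
                            read_id=f"s{i}") for i, r in enumerate(reads)]
        assert complexity(make_cluster(reads)) == pytest.approx(
            complexity(make_cluster(scaled))
        )


class TestPeakStats:
    def test_identical_reads_peak_fraction_one(self):
        pos, cov, frac = peak_stats(make_cluster(make_stack(100, 100)))
        assert (pos, cov, frac) == (100, 100.0, 1.0)

    def test_partial_peak_fraction(self):
        # 60 reads stacked at one locus, 40 elsewhere not covering it
        cluster = make_cluster(make_stack(100, 60) + make_stack(160, 40))
        pos, cov, frac = peak_stats(cluster)
        assert pos == 100
        assert cov == 60.0
        assert frac == pytest.approx(0.6)

    def test_tie_breaks_leftmost(self):
        cluster = make_cluster(make_stack(100, 50) + make_stack(200, 50))
        pos, _, _ = peak_stats(cluster)
        assert pos == 100

    def test_peak_fraction_one_iff_all_cover_modal_base(self):
        staggered = [make_read(100 + i, 140 + i, read_id=f"r{i}") for i in range(10)]
        pos, _, frac = peak_stats(make_cluster(staggered))
        assert frac == 1.0  # all reads overlap [109, 140)
        disjoint = make_cluster(make_stack(100, 6) + make_stack(200, 4))
        assert peak_stats(disjoint)[2] < 1.0


class TestConsensus:
    def test_single_read_returns_its_sequence(self):
        seq = "ACGTACGTACGTACGTACGTAC"
        cluster = make_cluster([make_read(100, 122, seq=seq)])
        assert consensus(cluster) == seq

    def test_identical_reads_reproduce_sequence(self):
        seq = "TTGCATTGCATTGCATTGCATT"
        reads = [make_read(100, 122, seq=seq, read_id=f"r{i}") for i in range(3)]
        assert consensus(make_cluster(reads)) == seq

    def test_majority_vote_column(self):
        reads = [
            make_read(100, 104, seq="AAAA", read_id="a1"),
            make_read(100, 104, seq="AAAA", read_id="a2"),
            make_read(100, 104, seq="CAAA", read_id="c1"),
        ]
        assert consensus(make_cluster(reads)) == "AAAA"

    def test_weighted_majority_and_tie_order(self):
        # weights 1+1 (C) vs 2 (A) tie at column 0 -> A wins by fixed order
        reads = [
            make_read(100, 102, seq="CG", read_id="c1"),
            make_read(100, 102, seq="CG", read_id="c2"),
            make_read(100, 102, seq="AG", weight=1.0, read_id="a1"),
            make_read(100, 102, seq="AG", weight=1.0, read_id="a2"),
        ]
        assert consensus(make_cluster(reads)) == "AG"

    def test_uncovered_columns_emit_n(self):
        # peak at the left stack; a long-spanning peak read reaches a region
        # covered by nobody else after a deletion
        reads = [
            make_read(100, 110, seq="ACGTACGTAC", read_id="p1"),
            make_read(100, 110, seq="ACGTACGTAC", read_id="p2"),
            make_read(100, 116, seq="ACGTACGTAC---AAA", read_id="gap"),
        ]
        out = consensus(make_cluster(reads))
        assert out == "ACGTACGTACNNNAAA"

    def test_spans_peak_supporting_reads_only(self):
        # the distal stack does not cover the peak; consensus ignores it
        peak = [make_read(100, 110, seq="GGGGGGGGGG", read_id=f"p{i}") for i in range(5)]
        distal = [make_read(150, 160, seq="TTTTTTTTTT", read_id=f"d{i}") for i in range(2)]
        assert consensus(make_cluster(peak + distal)) == "GGGGGGGGGG"


class TestCharacterize:
    def test_bundles_all_metrics(self):
        cluster = make_cluster(make_stack(100, 100, seq=None))
        u = characterize(cluster)
        assert u.ugr_id == "chr1:101-122"
        assert u.length == 22
        assert u.weighted_count == 100.0
        assert u.n_unique_reads == 100
        assert u.complexity == 0.0
        assert u.peak_fraction == 1.0
        assert u.n_distinct_sequences == 1

    def test_counts_multimapped_members(self):
        reads = make_stack(100, 99) + [
            make_read(100, 122, weight=0.5, read_id="mm", n_sites=2)
        ]
        u = characterize(make_cluster(reads))
        assert u.n_unique_reads == 99
        assert u.read_count == 100
        assert u.weighted_count == pytest.approx(99.5)


class TestCompareProperties:
    def test_identical_groups_high_p(self):
        a = [make_ugr(length=100 + i) for i in range(10)]
        out = compare_properties(a, list(a), "length")
        assert out.loc["length", "p_value"] > 0.9

    def test_complete_separation_exact_tail(self):
        a = [make_ugr(length=1000 + i) for i in range(20)]
        b = [make_ugr(length=100 + i) for i in range(20)]
        out = compare_properties(a, b, "length")
        assert out.loc["length", "p_value"] == pytest.approx(
            2 / math.comb(40, 20), rel=1e-9
        )

    def test_degenerate_data_flagged(self):
        a = [make_ugr(complexity=0.5) for _ in range(5)]
        b = [make_ugr(complexity=0.5) for _ in range(5)]
        out = compare_properties(a, b, "complexity")
        assert out.loc["complexity", "degenerate"]
        assert out.loc["complexity", "p_value"] == 1.0

    def test_bh_adjustment_over_properties(self):
        a = [make_ugr(length=1000 + i, complexity=0.9 - i * 1e-3) for i in range(15)]
        b = [make_ugr(length=100 + i, complexity=0.1 + i * 1e-3) for i in range(15)]
        out = compare_properties(a, b, ["length", "complexity"])
        assert set(out.index) == {"length", "complexity"}
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()

    def test_permuted_labels_give_uniform_p(self, rng):
        from scipy import stats as sps

        values = rng.normal(size=24)
        pvals = []
        for _ in range(400):
            perm = rng.permutation(values)
            a = [make_ugr(complexity=float(v)) for v in perm[:12]]
            b = [make_ugr(complexity=float(v)) for v in perm[12:]]
            pvals.append(
                float(compare_properties(a, b, "complexity").loc["complexity", "p_value"])
            )
        stat, _ = sps.kstest(pvals, "uniform")
        # discrete exact p-values are slightly super-uniform; loose bound
        assert stat < 0.12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_properties([], [make_ugr()], "length")
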