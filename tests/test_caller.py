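"""Gap-based cluster calling against a brute-force per-base oracle."""

from __future__ import annotations

import numpy as np
import pytest

from smrclust.caller import (
    CallerParams,
    UnsortedInputError,
    call_clusters,
    call_genome,
    merge_cluster_sets,
)

from conftest import make_cluster, make_read, make_stack


def brute_force_clusters(reads, min_gap, min_reads, count_mode="weighted"):
    """Per-base gap-closure oracle.

    Mark every base covered by a read footprint extended by ``min_gap - 1``
    on the right (so two reads land in one covered run exactly when the gap
    between them is below ``min_gap``); maximal covered runs are the
    candidate clusters; reads belong to the run containing their start.
    Returns (start, end, weighted_count) triples of clusters passing the
    threshold.
    """
    if not reads:
        return []
    hi = max(r.alignment.end for r in reads) + min_gap + 1
    covered = np.zeros(hi, dtype=bool)
    for r in reads:
        covered[r.alignment.start : r.alignment.end + min_gap - 1] = True
    run_id = np.full(hi, -1)
    current = -1
    for pos in range(hi):
        if covered[pos]:
            if pos == 0 or not covered[pos - 1]:
                current += 1
            run_id[pos] = current
    groups: dict[int, list] = {}
    for r in reads:
        groups.setdefault(int(run_id[r.alignment.start]), []).append(r)
    out = []
    for members in groups.values():
        count = (
            float(len(members))
            if count_mode == "reads"
            else sum(m.weight for m in members)
        )
        if count >= min_reads:
            out.append(
                (
                    min(m.alignment.start for m in members),
                    max(m.alignment.end for m in members),
                    sum(m.weight for m in members),
                )
            )
    return sorted(out)


class TestCallClusters:
    def test_stacks_closer_than_min_gap_merge(self):
        reads = make_stack(1000, 100) + make_stack(1096, 100)  # 74 bp gap
        clusters = call_clusters(reads)
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (1000, 1118)

    def test_min_gap_separates(self):
        reads = make_stack(1000, 100) + make_stack(1097, 100)  # 75 bp gap
        assert len(call_clusters(reads)) == 2

    def test_read_count_threshold_boundary(self):
        assert call_clusters(make_stack(1000, 99)) == []
        clusters = call_clusters(make_stack(1000, 100))
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (1000, 1022)

    def test_weighted_threshold_counts_fractions(self):
        # 200 half-weight reads carry 100 units of mass
        reads = [
            make_read(1000, 1022, weight=0.5, read_id=f"h{i}") for i in range(200)
        ]
        assert len(call_clusters(reads)) == 1
        assert call_clusters(reads[:198]) == []  # 99 units

    def test_count_mode_reads_ignores_weights(self):
        reads = [
            make_read(1000, 1022, weight=0.2, read_id=f"h{i}") for i in range(100)
        ]
        assert call_clusters(reads) == []
        assert len(call_clusters(reads, CallerParams(count_mode="reads"))) == 1

    def test_unsorted_input_raises(self):
        reads = [make_read(500), make_read(100)]
        with pytest.raises(UnsortedInputError):
            call_clusters(reads)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        params_grid = [(75, 100), (75, 10), (20, 5), (150, 50)]
        for trial in range(100):
            min_gap, min_reads = params_grid[trial % len(params_grid)]
            n = int(rng.integers(1, 500))
            reads = []
            for i in range(n):
                start = int(rng.integers(0, 3000))
                length = int(rng.integers(15, 41))
                weight = float(rng.uniform(0.05, 1.0))
                reads.append(
                    make_read(start, start + length, weight=weight, read_id=f"r{i}")
                )
            reads.sort(key=lambda r: (r.alignment.start, r.alignment.end))
            got = [
                (c.start, c.end, c.weighted_count)
                for c in call_clusters(
                    reads, CallerParams(min_gap=min_gap, min_reads=min_reads)
                )
            ]
            expected = brute_force_clusters(reads, min_gap, min_reads)
            assert [(s, e) for s, e, _ in got] == [(s, e) for s, e, _ in expected]
            for (_, _, wg), (_, _, we) in zip(got, expected):
                assert wg == pytest.approx(we)

    def test_separation_and_idempotence_properties(self, rng):
        reads = []
        for i in range(400):
            start = int(rng.integers(0, 2000))
            reads.append(make_read(start, start + 22, read_id=f"r{i}"))
        reads.sort(key=lambda r: (r.alignment.start, r.alignment.end))
        params = CallerParams(min_gap=50, min_reads=20)
        clusters = call_clusters(reads, params)
        for a, b in zip(clusters, clusters[1:]):
            assert b.start - a.end >= params.min_gap
        for c in clusters:
            again = call_clusters(
                sorted(c.members, key=lambda r: r.alignment.start), params
            )
            assert len(again) == 1
            assert (again[0].start, again[0].end) == (c.start, c.end)
        # total reported mass never exceeds the input mass
        total = sum(c.weighted_count for c in clusters)
        assert total <= sum(r.weight for r in reads) + 1e-9

    def test_threshold_and_gap_monotonicity(self, rng):
        reads = []
        for i in range(300):
            start = int(rng.integers(0, 1500))
            reads.append(make_read(start, start + 22, read_id=f"r{i}"))
        reads.sort(key=lambda r: (r.alignment.start, r.alignment.end))
        lenient = {
            (c.start, c.end)
            for c in call_clusters(reads, CallerParams(min_gap=60, min_reads=10))
        }
        strict = {
            (c.start, c.end)
            for c in call_clusters(reads, CallerParams(min_gap=60, min_reads=40))
        }
        assert strict <= lenient
        n_by_gap = [
            len(call_clusters(reads, CallerParams(min_gap=g, min_reads=10)))
            for g in (10, 30, 60, 120)
        ]
        assert all(a >= b for a, b in zip(n_by_gap, n_by_gap[1:]))

    def test_stranded_mode_splits_strands(self):
        plus = make_stack(1000, 100, strand="+")
        minus = [
            make_read(1005, 1027, strand="-", read_id=f"m{i}") for i in range(100)
        ]
        reads = sorted(plus + minus, key=lambda r: r.alignment.start)
        assert len(call_genome(reads, CallerParams(stranded=True))) == 2
        assert len(call_genome(reads, CallerParams(stranded=False))) == 1


class TestMergeClusterSets:
    def test_single_sample_unchanged(self):
        clusters = call_clusters(make_stack(1000, 100))
        merged = merge_cluster_sets({"s1": clusters})
        assert [(m.chrom, m.start, m.end) for m in merged] == [("chr1", 1000, 1022)]
        assert merged[0].samples == ("s1",)

    def test_overlapping_intervals_union(self):
        a = make_cluster(make_stack(100, 5, length=100))  # [100, 200)
        b = make_cluster(make_stack(150, 5, length=150))  # [150, 300)
        merged = merge_cluster_sets({"s1": [a], "s2": [b]})
        assert [(m.start, m.end) for m in merged] == [(100, 300)]
        assert merged[0].samples == ("s1", "s2")

    def test_book_ended_intervals_not_merged(self):
        a = make_cluster(make_stack(100, 5, length=100))  # [100, 200)
        b = make_cluster(make_stack(200, 5, length=100))  # [200, 300)
        merged = merge_cluster_sets({"s1": [a], "s2": [b]})
        assert len(merged) == 2

    def test_pooled_clusters_cover_merged_intervals(self, rng):
        """Pooled-mode calling covers every interval of per-half merging."""
        reads = []
        for i in range(400):
            start = int(rng.integers(0, 2000))
            reads.append(make_read(start, start + 22, read_id=f"r{i}"))
        reads.sort(key=lambda r: r.alignment.start)
        halves = {"a": reads[0::2], "b": reads[1::2]}
        params = CallerParams(min_gap=50, min_reads=30)
        per_half = {
            s: call_clusters(sorted(h, key=lambda r: r.alignment.start), params)
            for s, h in halves.items()
        }
        merged = merge_cluster_sets(per_half)
        pooled = call_clusters(reads, params)
        for interval in merged:
            assert any(
                c.start <= interval.start and c.end >= interval.end for c in pooled
            ), f"merged interval {interval} not covered by pooled clusters"
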