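"""Gap-based calling of small read clusters (smRCs / UGRs).

A cluster is a maximal run of weighted reads in which consecutive reads are
separated by less than ``min_gap`` bases (gap measured from the running
maximum end of the open cluster to the next read's start; overlapping or
book-ended reads always join).  Clusters whose total weighted read count is
below ``min_reads`` are discarded.  The defaults — 75 bp minimum separation
and 100 reads — reflect the typical trimmed small-RNA read length and the
minimum coverage at which annotated small-RNA loci are reliably detected.

Calling is annotation-free: clusters are reported wherever reads accumulate,
inside or outside known genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignment_io import WeightedRead

DEFAULT_MIN_GAP = 75
DEFAULT_MIN_READS = 100

UNSTRANDED = "."


@dataclass
class CallerParams:
    min_gap: int = DEFAULT_MIN_GAP
    min_reads: float = DEFAULT_MIN_READS
    stranded: bool = False
    #: "weighted" sums fractional rescue weights; "reads" counts each
    #: retained read once regardless of its weight.
    count_mode: str = "weighted"

    def __post_init__(self) -> None:
        if self.min_gap < 1:
            raise ValueError("min_gap must be >= 1")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.count_mode not in ("weighted", "reads"):
            raise ValueError("count_mode must be 'weighted' or 'reads'")


@dataclass
class RawCluster:
    chrom: str
    start: int
    end: int
    strand: str
    members: list[WeightedRead] = field(default_factory=list)

    @property
    def weighted_count(self) -> float:
        return sum(m.weight for m in self.members)

    @property
    def read_count(self) -> int:
        return len(self.members)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cluster_id(self) -> str:
        """Human-readable 1-based inclusive locus string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


class UnsortedInputError(ValueError):
    """Reads must be sorted by start position; sort the input and retry."""


def _count(members: Sequence[WeightedRead], mode: str) -> float:
    if mode == "reads":
        return float(len(members))
    return sum(m.weight for m in members)


def call_clusters(
    reads: Sequence[WeightedRead],
    params: CallerParams | None = None,
) -> list[RawCluster]:
    """Cluster the sorted weighted reads of one chromosome (and strand).

    Two consecutive reads fall in the same cluster iff
    ``next.start - running_max_end < min_gap``; any two reported clusters are
    therefore separated by at least ``min_gap`` bases.  Clusters below the
    ``min_reads`` threshold are dropped, never merged into neighbours.
    """
    params = params or CallerParams()
    if not reads:
        return []
    chroms = {r.alignment.chrom for r in reads}
    if len(chroms) != 1:
        raise ValueError("call_clusters expects reads of a single chromosome; "
                         "use call_genome for mixed input")
    strands = {r.alignment.strand for r in reads}
    if params.stranded and len(strands) != 1:
        raise ValueError("stranded calling expects reads of a single strand")
    strand = strands.pop() if len(strands) == 1 and params.stranded else UNSTRANDED

    clusters: list[RawCluster] = []
    members: list[WeightedRead] = [reads[0]]
    max_end = reads[0].alignment.end
    prev_start = reads[0].alignment.start
    for read in reads[1:]:
        a = read.alignment
        if a.start < prev_start:
            raise UnsortedInputError(
                "reads are not sorted by start position; sort the input first")
        prev_start = a.start
        if a.start - max_end < params.min_gap:
            members.append(read)
            max_end = max(max_end, a.end)
        else:
            clusters.append(_finish(members, strand))
            members = [read]
            max_end = a.end
    clusters.append(_finish(members, strand))
    return [c for c in clusters if _count(c.members, params.count_mode) >= params.min_reads]


def _finish(members: list[WeightedRead], strand: str) -> RawCluster:
    start = min(m.alignment.start for m in members)
    end = max(m.alignment.end for m in members)
    chrom = members[0].alignment.chrom
    return RawCluster(chrom=chrom, start=start, end=end, strand=strand, members=members)


def call_genome(
    reads: Iterable[WeightedRead],
    params: CallerParams | None = None,
) -> list[RawCluster]:
    """Call clusters over a whole genome's weighted reads (any order).

    Reads are partitioned by chromosome — and by strand when
    ``params.stranded`` — sorted, and clustered per partition.  Output is in
    coordinate order.
    """
    params = params or CallerParams()
    partitions: dict[tuple, list[WeightedRead]] = {}
    for read in reads:
        a = read.alignment
        key = (a.chrom, a.strand) if params.stranded else (a.chrom,)
        partitions.setdefault(key, []).append(read)
    out: list[RawCluster] = []
    for key in sorted(partitions):
        part = sorted(partitions[key], key=lambda w: (w.alignment.start, w.alignment.end))
        out.extend(call_clusters(part, params))
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return out


@dataclass(frozen=True)
class UnifiedInterval:
    """One interval of the unified cluster set with its contributing samples."""

    chrom: str
    start: int
    end: int
    strand: str
    samples: tuple[str, ...]

    @property
    def interval_id(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def merge_cluster_sets(
    cluster_sets: dict[str, Sequence[RawCluster]],
    stranded: bool = False,
) -> list[UnifiedInterval]:
    """Union per-sample cluster intervals into one shared locus set.

    Intervals overlapping by at least 1 bp (same chromosome, and same strand
    when ``stranded``) are merged; the result is sorted and non-overlapping,
    and each unified interval records which samples contributed to it.
    """
    if not cluster_sets:
        raise ValueError("at least one cluster set is required")
    entries = []
    for sample, clusters in cluster_sets.items():
        for c in clusters:
            key = (c.chrom, c.strand) if stranded else (c.chrom, UNSTRANDED)
            entries.append((key, c.start, c.end, sample))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    merged: list[UnifiedInterval] = []
    i = 0
    while i < len(entries):
        key, start, end, sample = entries[i]
        samples = {sample}
        j = i + 1
        while j < len(entries) and entries[j][0] == key and entries[j][1] < end:
            end = max(end, entries[j][2])
            samples.add(entries[j][3])
            j += 1
        merged.append(
            UnifiedInterval(key[0], start, end, key[1], tuple(sorted(samples)))
        )
        i = j
    merged.sort(key=lambda u: (u.chrom, u.start, u.end, u.strand))
    return merged
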