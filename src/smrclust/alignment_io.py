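"""Alignment ingestion and multi-mapping read rescue.

Small-RNA reads are short (15-75 nt) and frequently align to several genomic
sites (rRNA fragments, duplicated miRNA loci, repeats).  Discarding them
biases cluster discovery; assigning each site a full count inflates it.  This
module implements the single-pass *multimap rescue* used throughout the
package: each multimapped read is distributed fractionally across its
retained sites in proportion to the local depth of uniquely mapped reads,
falling back to an even split when no unique signal is available nearby.

Reads reported at more than ``max_sites`` alignment sites (default 15) are
discarded outright as unmappable.  Coordinates are 0-based half-open
throughout.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

DEFAULT_MAX_SITES = 15

# CIGAR operators that this small-RNA model does not support: N (ref skip)
# and P (padding).  Records containing them are skipped with a counted
# warning rather than mis-projected.
_UNSUPPORTED_CIGAR_OPS = {3, 6}


@dataclass(frozen=True)
class ReadAlignment:
    """One alignment site of a read.

    ``ref_sequence`` is the read projected onto reference coordinates: a
    string of length ``end - start`` whose column *k* holds the read base
    aligned to reference position ``start + k``, or ``-`` where the read has
    a deletion.  Insertions in the read are dropped by the projection and
    soft-clipped bases never appear.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    ref_sequence: str
    n_sites: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_unique(self) -> bool:
        return self.n_sites == 1


@dataclass(frozen=True)
class WeightedRead:
    alignment: ReadAlignment
    weight: float

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0 + 1e-9):
            raise ValueError(f"weight {self.weight} outside (0, 1]")


@dataclass
class RescueParams:
    max_sites: int = DEFAULT_MAX_SITES
    rescue_window: int = 0

    def __post_init__(self) -> None:
        if self.max_sites < 1:
            raise ValueError("max_sites must be >= 1")
        if self.rescue_window < 0:
            raise ValueError("rescue_window must be >= 0")


@dataclass
class LoadStats:
    """Per-file ingestion counters, reported in the run manifest."""

    records_seen: int = 0
    unmapped_skipped: int = 0
    cigar_skipped: int = 0
    reads_retained: int = 0
    reads_discarded_max_sites: int = 0
    warnings: list = field(default_factory=list)


def _project_record(rec: pysam.AlignedSegment) -> str:
    """Project a record's query sequence onto its reference footprint."""
    start, end = rec.reference_start, rec.reference_end
    cols = ["-"] * (end - start)
    seq = rec.query_sequence
    if seq is None:
        return "".join(cols)
    for qpos, rpos in rec.get_aligned_pairs(matches_only=False):
        if rpos is None or rpos < start or rpos >= end:
            continue
        if qpos is not None:
            cols[rpos - start] = seq[qpos]
    return "".join(cols)


def _record_to_alignment(rec: pysam.AlignedSegment, n_sites: int) -> ReadAlignment:
    return ReadAlignment(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        ref_sequence=_project_record(rec),
        n_sites=n_sites,
    )


def load_alignments(
    path: str,
    params: RescueParams | None = None,
    stats: LoadStats | None = None,
) -> Iterator[list[ReadAlignment]]:
    """Yield the retained alignment sites of each read, grouped by read id.

    The whole file is scanned once; unmapped records are skipped, records
    with unsupported CIGAR operators (reference skips, padding) are skipped
    with a counted warning, and reads whose site count exceeds
    ``params.max_sites`` are discarded entirely.  The per-read site count is
    taken from the ``NH`` tag when present and consistent, else from the
    number of records sharing the read id.  Secondary, supplementary and
    duplicate-flagged records all count as candidate sites: small-RNA stacks
    are legitimate duplicates.
    """
    params = params or RescueParams()
    stats = stats if stats is not None else LoadStats()
    groups: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    save = pysam.set_verbosity(0)  # silence missing-index chatter
    try:
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for rec in fh:
                stats.records_seen += 1
                if rec.is_unmapped or rec.reference_name is None:
                    stats.unmapped_skipped += 1
                    continue
                if any(op in _UNSUPPORTED_CIGAR_OPS for op, _ in (rec.cigartuples or [])):
                    stats.cigar_skipped += 1
                    if stats.cigar_skipped == 1:
                        msg = f"{path}: skipping record(s) with N/P CIGAR operators"
                        stats.warnings.append(msg)
                        logger.warning(msg)
                    continue
                groups[rec.query_name].append(rec)
    finally:
        pysam.set_verbosity(save)

    for read_id, recs in groups.items():
        nh_tags = {rec.get_tag("NH") for rec in recs if rec.has_tag("NH")}
        n_sites = max(nh_tags) if nh_tags else len(recs)
        n_sites = max(n_sites, len(recs))
        if n_sites > params.max_sites:
            stats.reads_discarded_max_sites += 1
            continue
        stats.reads_retained += 1
        yield [_record_to_alignment(rec, n_sites) for rec in recs]


class UniqueDepth:
    """Per-base depth of uniquely mapped reads, one dense track per chromosome."""

    def __init__(self) -> None:
        self._tracks: dict[str, np.ndarray] = {}

    @classmethod
    def from_alignments(cls, alignments: Iterable[ReadAlignment]) -> "UniqueDepth":
        depth = cls()
        for aln in alignments:
            if aln.is_unique:
                depth.add(aln.chrom, aln.start, aln.end)
        return depth

    def _track(self, chrom: str, min_len: int) -> np.ndarray:
        track = self._tracks.get(chrom)
        if track is None:
            track = np.zeros(max(min_len, 1024), dtype=np.float64)
            self._tracks[chrom] = track
        elif len(track) < min_len:
            track = np.concatenate([track, np.zeros(min_len - len(track))])
            self._tracks[chrom] = track
        return track

    def add(self, chrom: str, start: int, end: int, weight: float = 1.0) -> None:
        self._track(chrom, end)[start:end] += weight

    def depth_at(self, chrom: str, pos: int) -> float:
        track = self._tracks.get(chrom)
        if track is None or pos >= len(track):
            return 0.0
        return float(track[pos])

    def mean_depth(self, chrom: str, start: int, end: int, window: int = 0) -> float:
        """Mean unique depth over [start - window, end + window)."""
        lo, hi = max(0, start - window), end + window
        track = self._tracks.get(chrom)
        if track is None:
            return 0.0
        covered = track[lo:min(hi, len(track))]
        total = float(covered.sum())
        return total / (hi - lo)


def rescue_multimapped(
    sites: Sequence[ReadAlignment],
    udepth: UniqueDepth,
    rescue_window: int = 0,
) -> list[WeightedRead]:
    """Distribute one read's count across its sites by unique-read depth.

    The weight of site *i* is ``u_i / sum(u_j)`` where ``u_i`` is the mean
    unique-read depth over the site's footprint (optionally extended by
    ``rescue_window`` bp on each side).  When no site sees any unique depth
    the read is split evenly.  Weights always sum to 1.
    """
    if not sites:
        return []
    if len({s.read_id for s in sites}) != 1:
        raise ValueError("sites must all belong to one read")
    k = len(sites)
    if k == 1:
        return [WeightedRead(sites[0], 1.0)]
    u = np.array(
        [udepth.mean_depth(s.chrom, s.start, s.end, window=rescue_window) for s in sites]
    )
    total = u.sum()
    weights = u / total if total > 0 else np.full(k, 1.0 / k)
    # sites attracting no mass are dropped; the remainder still sums to 1
    return [WeightedRead(s, float(w)) for s, w in zip(sites, weights) if w > 0]


def load_weighted_reads(
    path: str,
    params: RescueParams | None = None,
    stats: LoadStats | None = None,
) -> tuple[list[WeightedRead], LoadStats]:
    """Full ingestion: load, compute unique depth, rescue, return weighted reads.

    The returned list is sorted by (chrom, start, end) so it can feed the
    cluster caller directly.  ``stats.reads_retained`` is the library size
    (total weight) of the sample.
    """
    params = params or RescueParams()
    stats = stats if stats is not None else LoadStats()
    groups = list(load_alignments(path, params, stats))
    udepth = UniqueDepth.from_alignments(
        aln for group in groups for aln in group if aln.is_unique
    )
    weighted: list[WeightedRead] = []
    for group in groups:
        weighted.extend(rescue_multimapped(group, udepth, params.rescue_window))
    weighted.sort(key=lambda w: (w.alignment.chrom, w.alignment.start, w.alignment.end))
    return weighted, stats


def write_weighted_tsv(weighted: Iterable[WeightedRead], path: str) -> None:
    """Debug export: one weighted alignment site per line."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\tweight\n")
        for w in weighted:
            a = w.alignment
            fh.write(
                f"{a.read_id}\t{a.chrom}\t{a.start}\t{a.end}\t{a.strand}\t{w.weight:.9g}\n"
            )
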