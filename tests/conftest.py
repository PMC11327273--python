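"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from smrclust.alignment_io import ReadAlignment, WeightedRead
from smrclust.caller import RawCluster
from smrclust.metrics import UGR


def make_read(
    start: int,
    end: int | None = None,
    chrom: str = "chr1",
    weight: float = 1.0,
    read_id: str | None = None,
    seq: str | None = None,
    strand: str = "+",
    n_sites: int = 1,
) -> WeightedRead:
    """A unit-weight aligned read with a synthetic all-A sequence by default."""
    if end is None:
        end = start + 22
    if seq is None:
        seq = "A" * (end - start)
    if read_id is None:
        read_id = f"r_{chrom}_{start}_{end}_{strand}"
    return WeightedRead(
        ReadAlignment(read_id, chrom, start, end, strand, seq, n_sites), weight
    )


def make_stack(start: int, n: int, length: int = 22, **kw) -> list[WeightedRead]:
    """n identical unit-weight reads sharing one footprint."""
    return [
        make_read(start, start + length, read_id=f"stack_{start}_{i}", **kw)
        for i in range(n)
    ]


def make_cluster(members: list[WeightedRead], strand: str = ".") -> RawCluster:
    return RawCluster(
        chrom=members[0].alignment.chrom,
        start=min(m.alignment.start for m in members),
        end=max(m.alignment.end for m in members),
        strand=strand,
        members=members,
    )


def make_ugr(**overrides) -> UGR:
    """A UGR record with plausible defaults, for property-comparison tests."""
    base = dict(
        chrom="chr1", start=100, end=300, strand=".", length=200,
        weighted_count=150.0, read_count=150, n_unique_reads=140,
        n_distinct_sequences=30, complexity=0.2, peak_pos=150,
        peak_coverage=60.0, peak_fraction=0.4, consensus="ACGT",
    )
    base.update(overrides)
    return UGR(**base)


def write_sam(
    path,
    records: list[tuple],
    chrom_lengths: dict[str, int] | None = None,
) -> str:
    """Write a SAM file from (name, chrom, start, seq, nh, flag[, cigar]) tuples."""
    chrom_lengths = chrom_lengths or {"chr1": 100_000, "chr2": 100_000}
    chroms = sorted(chrom_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}
    recs = []
    for entry in records:
        name, chrom, start, seq, nh, flag = entry[:6]
        cigar = entry[6] if len(entry) > 6 else f"{len(seq)}M"
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.query_sequence = seq
        rec.reference_id = tid[chrom]
        rec.reference_start = start
        rec.cigarstring = cigar
        rec.flag = flag
        rec.mapping_quality = 60
        if nh is not None:
            rec.set_tag("NH", nh)
        recs.append(rec)
    recs.sort(key=lambda r: (r.reference_id, r.reference_start))
    path = str(path)
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for rec in recs:
            fh.write(rec)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
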