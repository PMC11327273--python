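"""Adapter trimming of raw small-RNA reads.

Small-RNA library preparations that use template-switching chemistry leave a
triad of three non-templated bases on the 5' end of every read and a poly(A)
homopolymer (from the oligo-dT priming) followed by the sequencing adapter on
the 3' end.  Preparation therefore consists of three steps applied in order:

1. unconditionally remove the first ``head_trim`` bases (default 3);
2. locate the leftmost occurrence of the 3' adapter (default ``AAAAAAAAAA``)
   and remove it together with everything 3' of it; partial adapter matches
   hanging off the 3' end of the read are trimmed as well;
3. discard the read when fewer than ``min_length`` bases remain (default 15).

Adapter matching follows the standard 3'-adapter convention: a candidate
occurrence at offset *i* covers ``L = min(len(adapter), len(read) - i)``
adapter bases and is accepted when ``L >= min_overlap`` and the number of
mismatches is at most ``floor(error_rate * L)``.  ``N`` bases never match.
Among accepted occurrences the one with the most matching bases wins (so an
exact full-length hit beats an earlier near-miss), ties prefer fewer
errors, then the leftmost offset.  With the default 10% error rate this
means partial 3'-end overlaps must be exact (any overlap shorter than ten
bases allows zero errors) while a full-length internal occurrence tolerates
one mismatch.  Indels are not modeled; for a homopolymer adapter an indel is
indistinguishable from a mismatch/shift.

Quality strings are truncated in lockstep with the sequence and never
otherwise modified.
"""

from __future__ import annotations

import gzip
import json
import sys
from dataclasses import dataclass
from typing import Iterator, TextIO

import pysam

DEFAULT_ADAPTER = "AAAAAAAAAA"
DEFAULT_HEAD_TRIM = 3
DEFAULT_MIN_LENGTH = 15
DEFAULT_ERROR_RATE = 0.1
DEFAULT_MIN_OVERLAP = 3


class MalformedReadError(ValueError):
    """Sequence and quality strings differ in length, or the sequence is empty."""


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    qualities: str

    def validate(self) -> None:
        if not self.sequence:
            raise MalformedReadError(f"{self.read_id}: empty sequence")
        if len(self.sequence) != len(self.qualities):
            raise MalformedReadError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class TrimResult:
    kept: bool
    trimmed_sequence: str
    trimmed_qualities: str


def find_adapter(
    sequence: str,
    adapter: str,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> int:
    """Return the start offset of the best acceptable adapter occurrence.

    Best = most matching bases, then fewest errors, then leftmost.  Returns
    -1 when no occurrence satisfies the overlap and error-rate constraints.
    See the module docstring for the matching rules.
    """
    n = len(sequence)
    m = len(adapter)
    best = -1
    best_key = None
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        allowed = int(error_rate * overlap)
        mismatches = 0
        ok = True
        for j in range(overlap):
            s = sequence[i + j]
            a = adapter[j]
            if s != a or s == "N" or a == "N":
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            key = (overlap - mismatches, -mismatches, -i)
            if best_key is None or key > best_key:
                best, best_key = i, key
    return best


def trim_read(
    read: RawRead,
    head_trim: int = DEFAULT_HEAD_TRIM,
    adapter: str = DEFAULT_ADAPTER,
    min_length: int = DEFAULT_MIN_LENGTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> TrimResult:
    """Trim one read: head bases, then 3' adapter, then length filter."""
    if head_trim < 0:
        raise ValueError("head_trim must be >= 0")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    read.validate()

    seq = read.sequence[head_trim:]
    qual = read.qualities[head_trim:]
    hit = find_adapter(seq, adapter, error_rate=error_rate, min_overlap=min_overlap)
    if hit >= 0:
        seq = seq[:hit]
        qual = qual[:hit]
    if len(seq) < min_length:
        return TrimResult(kept=False, trimmed_sequence="", trimmed_qualities="")
    return TrimResult(kept=True, trimmed_sequence=seq, trimmed_qualities=qual)


def _open_out(path: str) -> TextIO:
    if path == "-":
        return sys.stdout
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def read_fastq(path: str) -> Iterator[RawRead]:
    """Iterate a (possibly gzipped) FASTQ file as :class:`RawRead` records."""
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            yield RawRead(rec.name, rec.sequence or "", rec.quality or "")


def trim_fastq(
    in_path: str,
    out_path: str,
    head_trim: int = DEFAULT_HEAD_TRIM,
    adapter: str = DEFAULT_ADAPTER,
    min_length: int = DEFAULT_MIN_LENGTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    report_path: str | None = None,
) -> dict:
    """Trim a whole FASTQ file, returning (and optionally writing) a report.

    Malformed records are rejected individually and counted; they never abort
    the run.
    """
    n_in = n_kept = n_discarded = n_malformed = 0
    out = _open_out(out_path)
    try:
        for read in read_fastq(in_path):
            n_in += 1
            try:
                res = trim_read(
                    read,
                    head_trim=head_trim,
                    adapter=adapter,
                    min_length=min_length,
                    error_rate=error_rate,
                    min_overlap=min_overlap,
                )
            except MalformedReadError:
                n_malformed += 1
                continue
            if res.kept:
                n_kept += 1
                out.write(
                    f"@{read.read_id}\n{res.trimmed_sequence}\n+\n{res.trimmed_qualities}\n"
                )
            else:
                n_discarded += 1
    finally:
        if out is not sys.stdout:
            out.close()
    report = {
        "input_reads": n_in,
        "kept_reads": n_kept,
        "discarded_short": n_discarded,
        "malformed_records": n_malformed,
        "parameters": {
            "head_trim": head_trim,
            "adapter": adapter,
            "min_length": min_length,
            "error_rate": error_rate,
            "min_overlap": min_overlap,
        },
    }
    if report_path:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
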