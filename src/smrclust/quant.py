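"""Cross-sample quantification of the unified cluster set.

Each sample's weighted reads are counted against the shared, non-overlapping
UGR intervals: a read is assigned to the single UGR it overlaps the most
(ties to the leftmost), never split or double-counted, so column sums are
bounded by library sizes.  The matrix then supports the standard small-RNA
expression workflow: counts-per-million (CPM), voom-style log2-CPM with a
0.5-read pseudo-count, an expression filter keeping loci with CPM above a
threshold in at least ``min_samples`` samples (within at least one phenotype
group when groups are supplied), and Spearman correlation of mean log2-CPM
profiles between sample sets.

Heavier modeling (TMM normalization, limma/voom differential expression) is
deliberately left to the dedicated statistics packages; the exporters here
write the raw counts and library sizes in the layout those tools ingest.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment_io import WeightedRead
from .caller import UnifiedInterval

DEFAULT_CPM_THRESHOLD = 10.0
DEFAULT_MIN_SAMPLES = 1
LOG2_PSEUDOCOUNT = 0.5


@dataclass
class FilterParams:
    cpm_threshold: float = DEFAULT_CPM_THRESHOLD
    min_samples: int = DEFAULT_MIN_SAMPLES

    def __post_init__(self) -> None:
        if self.cpm_threshold <= 0:
            raise ValueError("cpm_threshold must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class CountMatrix:
    """UGR x sample table of weighted counts with per-sample library sizes."""

    values: pd.DataFrame  # rows: ugr ids, cols: sample ids
    library_sizes: pd.Series  # per-sample total weighted retained reads
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("row and column ids must be unique")
        missing = set(self.values.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"library sizes missing for samples: {sorted(missing)}")
        short = self.values.sum(axis=0) > self.library_sizes[self.values.columns] + 1e-6
        if short.any():
            raise ValueError("column sum exceeds library size")


def _assign_read(
    read: WeightedRead,
    starts: np.ndarray,
    ends: np.ndarray,
) -> int | None:
    """Index of the UGR (within one chromosome) a read is assigned to.

    Candidate UGRs overlap the read by >= 1 bp; the one with the greater
    overlap wins, ties to the leftmost.  Intervals are sorted and
    non-overlapping, so candidates are contiguous in the arrays.
    """
    a = read.alignment
    lo = int(np.searchsorted(ends, a.start, side="right"))
    best = None
    best_bp = 0
    for i in range(lo, len(starts)):
        if starts[i] >= a.end:
            break
        bp = min(a.end, ends[i]) - max(a.start, starts[i])
        if bp > best_bp:
            best, best_bp = i, bp
    return best


def quantify(
    samples: Mapping[str, Sequence[WeightedRead]],
    ugrs: Sequence[UnifiedInterval],
    library_sizes: Mapping[str, float] | None = None,
    metadata: pd.DataFrame | None = None,
) -> CountMatrix:
    """Count each sample's weighted reads against the unified UGR set.

    ``library_sizes`` defaults to each sample's total read weight (correct
    when the passed reads are the sample's full retained set).
    """
    ids = [u.interval_id for u in ugrs]
    if len(set(ids)) != len(ids):
        raise ValueError("UGR ids must be unique")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    order = sorted(range(len(ugrs)), key=lambda i: (ugrs[i].chrom, ugrs[i].start))
    for i in order:
        u = ugrs[i]
        entry = by_chrom.setdefault(u.chrom, (list(), list(), list()))
        entry[0].append(u.start)
        entry[1].append(u.end)
        entry[2].append(i)
    for chrom, (starts, ends, idx) in list(by_chrom.items()):
        s, e = np.array(starts), np.array(ends)
        if ((s[1:] < e[:-1]).any()) if len(s) > 1 else False:
            raise ValueError("unified UGR intervals must be non-overlapping")
        by_chrom[chrom] = (s, e, idx)

    mat = np.zeros((len(ugrs), len(samples)))
    sample_ids = list(samples)
    lib = {}
    for j, sample in enumerate(sample_ids):
        reads = samples[sample]
        total = sum(r.weight for r in reads)
        lib[sample] = (
            library_sizes[sample] if library_sizes is not None else total
        )
        if total == 0:
            logging.getLogger(__name__).warning(
                "sample %s has zero retained reads; column of zeros", sample
            )
        for read in reads:
            entry = by_chrom.get(read.alignment.chrom)
            if entry is None:
                continue
            starts, ends, idx = entry
            hit = _assign_read(read, starts, ends)
            if hit is not None:
                mat[idx[hit], j] += read.weight
    values = pd.DataFrame(mat, index=ids, columns=sample_ids)
    return CountMatrix(
        values=values,
        library_sizes=pd.Series(lib, dtype=float),
        metadata=metadata if metadata is not None else pd.DataFrame(index=sample_ids),
    )


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million library reads."""
    lib = matrix.library_sizes[matrix.values.columns]
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    return 1e6 * matrix.values / lib


def log2_cpm(matrix: CountMatrix, prior: float = LOG2_PSEUDOCOUNT) -> pd.DataFrame:
    """voom-style log2-CPM: log2((count + prior) / (libsize + 2*prior) * 1e6)."""
    lib = matrix.library_sizes[matrix.values.columns]
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    out = np.log2((matrix.values + prior) / (lib + 2 * prior) * 1e6)
    out.attrs["log2_cpm_prior"] = prior
    return out


def filter_expressed(
    matrix: CountMatrix,
    params: FilterParams | None = None,
    groups: Mapping[str, str] | None = None,
) -> tuple[CountMatrix, dict]:
    """Drop under-expressed loci.

    A locus is kept when at least ``min_samples`` samples have
    CPM > ``cpm_threshold``; when ``groups`` maps samples to phenotype
    groups, the ``min_samples`` quorum must be met within at least one group.
    """
    params = params or FilterParams()
    cpm_mat = cpm(matrix)
    above = cpm_mat > params.cpm_threshold
    if groups is None:
        keep = above.sum(axis=1) >= params.min_samples
    else:
        keep = pd.Series(False, index=cpm_mat.index)
        for group in set(groups.values()):
            cols = [s for s in cpm_mat.columns if groups.get(s) == group]
            if cols:
                keep |= above[cols].sum(axis=1) >= params.min_samples
    kept = matrix.values.loc[keep]
    report = {
        "n_input": int(matrix.values.shape[0]),
        "n_kept": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
        "cpm_threshold": params.cpm_threshold,
        "min_samples": params.min_samples,
    }
    return (
        CountMatrix(kept, matrix.library_sizes, matrix.metadata),
        report,
    )


def spearman_profile_correlation(
    matrix: CountMatrix,
    sample_set_a: Sequence[str],
    sample_set_b: Sequence[str],
) -> tuple[float, float]:
    """Spearman rho between the mean log2-CPM profiles of two sample sets.

    Returns (rho, p_value); (nan, nan) when either mean profile is constant
    (rank correlation undefined).
    """
    lmat = log2_cpm(matrix)
    if lmat.shape[0] < 3:
        raise ValueError("need at least 3 shared loci")
    a = lmat[list(sample_set_a)].mean(axis=1)
    b = lmat[list(sample_set_b)].mean(axis=1)
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        logging.getLogger(__name__).warning("constant profile; rho undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)


def write_matrix(matrix: CountMatrix, prefix: str) -> None:
    """Write counts, library sizes and metadata as TSV next to ``prefix``."""
    matrix.values.to_csv(f"{prefix}.counts.tsv", sep="\t", index_label="ugr_id")
    matrix.library_sizes.rename("library_size").to_csv(
        f"{prefix}.libsizes.tsv", sep="\t", index_label="sample"
    )
    if not matrix.metadata.empty:
        matrix.metadata.to_csv(f"{prefix}.metadata.tsv", sep="\t", index_label="sample")


def read_matrix(prefix: str) -> CountMatrix:
    values = pd.read_csv(f"{prefix}.counts.tsv", sep="\t", index_col="ugr_id")
    values.index.name = None
    lib = pd.read_csv(f"{prefix}.libsizes.tsv", sep="\t", index_col="sample")[
        "library_size"
    ]
    lib.index.name = None
    try:
        meta = pd.read_csv(f"{prefix}.metadata.tsv", sep="\t", index_col="sample")
    except FileNotFoundError:
        meta = pd.DataFrame(index=values.columns)
    return CountMatrix(values, lib, meta)
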