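"""Characterization metrics for called read clusters.

Three metrics summarize the internal structure of a cluster:

*complexity* — the Shannon entropy of the weighted read *start-position*
distribution, normalized by the log of the cluster span:

    complexity = -sum_b p_b ln p_b / ln(end - start)

where ``p_b`` is the fraction of the cluster's weighted read mass starting at
base ``b``.  A cluster whose reads all share one start scores exactly 0 (a
single read peak); equal-mass starts at every base of the span score exactly
1 (uniform tiling).  The normalizing log base cancels, so natural log is
used.

*peak coverage* — the weighted number of reads covering the cluster's
maximal-depth base (ties resolved to the leftmost base); *peak fraction* is
peak coverage divided by the cluster's total weighted count.

*consensus* — the per-column weighted-majority sequence over the reads that
support the peak, spanning from their leftmost start to their rightmost end.
Ties go to the alphabetically first base (A < C < G < T); columns with no
coverage emit ``N``.

All three are invariant under uniform rescaling of member weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .caller import RawCluster

logger = logging.getLogger(__name__)

_BASES = "ACGT"

COMPARABLE_PROPERTIES = (
    "length",
    "complexity",
    "peak_fraction",
    "n_unique_reads",
    "weighted_count",
)


@dataclass
class UGR:
    """A called cluster together with its characterization metrics."""

    chrom: str
    start: int
    end: int
    strand: str
    length: int
    weighted_count: float
    read_count: int
    n_unique_reads: int
    n_distinct_sequences: int
    complexity: float
    peak_pos: int
    peak_coverage: float
    peak_fraction: float
    consensus: str

    @property
    def ugr_id(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def complexity(cluster: RawCluster) -> float:
    """Normalized start-position entropy of a cluster, in [0, 1]."""
    if not cluster.members:
        raise ValueError("cluster has no members")
    span = cluster.end - cluster.start
    mass: dict[int, float] = {}
    for m in cluster.members:
        mass[m.alignment.start] = mass.get(m.alignment.start, 0.0) + m.weight
    if span <= 1 or len(mass) == 1:
        return 0.0
    w = np.array(list(mass.values()))
    total = w.sum()
    # H = ln W - (sum w ln w) / W; algebraically identical to -sum p ln p but
    # exact (0 * ln 1 terms vanish) when all masses are 1, so the uniform
    # length-1 tiling endpoint scores exactly 1.
    h = float(np.log(total) - (w * np.log(w)).sum() / total)
    return min(h / float(np.log(span)), 1.0)


def peak_stats(cluster: RawCluster) -> tuple[int, float, float]:
    """(peak_pos, peak_coverage, peak_fraction) of a cluster.

    The peak is the base of maximal weighted depth; ties break leftmost.
    """
    if not cluster.members:
        raise ValueError("cluster has no members")
    span = cluster.end - cluster.start
    depth = np.zeros(span)
    for m in cluster.members:
        a = m.alignment
        depth[a.start - cluster.start : a.end - cluster.start] += m.weight
    peak_pos = cluster.start + int(np.argmax(depth))
    peak_coverage = sum(
        m.weight for m in cluster.members if m.alignment.start <= peak_pos < m.alignment.end
    )
    return peak_pos, peak_coverage, peak_coverage / cluster.weighted_count


def consensus(cluster: RawCluster, peak_pos: int | None = None) -> str:
    """Weighted-majority consensus over the reads covering the cluster peak."""
    if peak_pos is None:
        peak_pos, _, _ = peak_stats(cluster)
    peak_reads = [
        m for m in cluster.members if m.alignment.start <= peak_pos < m.alignment.end
    ]
    with_seq = [m for m in peak_reads if m.alignment.ref_sequence.strip("-")]
    if not with_seq:
        logger.warning("all peak-supporting reads lack sequence; empty consensus")
        return ""
    lo = min(m.alignment.start for m in with_seq)
    hi = max(m.alignment.end for m in with_seq)
    votes = np.zeros((hi - lo, len(_BASES)))
    for m in with_seq:
        a = m.alignment
        for k, base in enumerate(a.ref_sequence):
            idx = _BASES.find(base)
            if idx >= 0:
                votes[a.start - lo + k, idx] += m.weight
    out = []
    for col in votes:
        if col.sum() == 0:
            out.append("N")
        else:
            out.append(_BASES[int(np.argmax(col))])  # argmax tie -> A<C<G<T
    return "".join(out)


def characterize(cluster: RawCluster) -> UGR:
    """Compute every metric of one cluster and bundle it as a :class:`UGR`."""
    peak_pos, peak_cov, peak_frac = peak_stats(cluster)
    seqs = {
        m.alignment.ref_sequence for m in cluster.members if m.alignment.ref_sequence
    }
    return UGR(
        chrom=cluster.chrom,
        start=cluster.start,
        end=cluster.end,
        strand=cluster.strand,
        length=cluster.length,
        weighted_count=cluster.weighted_count,
        read_count=cluster.read_count,
        n_unique_reads=sum(1 for m in cluster.members if m.alignment.is_unique),
        n_distinct_sequences=len(seqs),
        complexity=complexity(cluster),
        peak_pos=peak_pos,
        peak_coverage=peak_cov,
        peak_fraction=peak_frac,
        consensus=consensus(cluster, peak_pos),
    )


def metrics_table(ugrs: Sequence[UGR]) -> pd.DataFrame:
    """One row per UGR with all metric fields, indexed by UGR id."""
    rows = [
        {
            "ugr_id": u.ugr_id,
            "chrom": u.chrom,
            "start": u.start,
            "end": u.end,
            "strand": u.strand,
            "length": u.length,
            "weighted_count": u.weighted_count,
            "read_count": u.read_count,
            "n_unique_reads": u.n_unique_reads,
            "n_distinct_sequences": u.n_distinct_sequences,
            "complexity": u.complexity,
            "peak_pos": u.peak_pos,
            "peak_coverage": u.peak_coverage,
            "peak_fraction": u.peak_fraction,
            "consensus": u.consensus,
        }
        for u in ugrs
    ]
    return pd.DataFrame(rows).set_index("ugr_id") if rows else pd.DataFrame()


def compare_properties(
    group_a: Sequence[UGR],
    group_b: Sequence[UGR],
    properties: str | Sequence[str] = COMPARABLE_PROPERTIES,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of UGR properties between groups.

    Returns a table with one row per property: the Mann-Whitney U statistic,
    the two-sided p-value, the Benjamini-Hochberg adjusted p-value (when more
    than one property is tested) and a flag for degenerate (constant pooled)
    data, for which p is reported as 1.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if isinstance(properties, str):
        properties = [properties]
    rows = []
    for prop in properties:
        x = np.array([getattr(u, prop) for u in group_a], dtype=float)
        y = np.array([getattr(u, prop) for u in group_b], dtype=float)
        degenerate = np.ptp(np.concatenate([x, y])) == 0
        if degenerate:
            stat, p = np.nan, 1.0
        else:
            pooled = np.concatenate([x, y])
            no_ties = len(np.unique(pooled)) == len(pooled)
            method = "exact" if no_ties and min(len(x), len(y)) <= 25 else "asymptotic"
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {"property": prop, "statistic": stat, "p_value": p, "degenerate": degenerate}
        )
    out = pd.DataFrame(rows).set_index("property")
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
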