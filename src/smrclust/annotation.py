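"""Annotation of called clusters against a reference gene model.

Each cluster is labeled *annotated* when it overlaps any gene feature by at
least one base pair (no fraction threshold; the overlap fraction is reported
so users can re-threshold downstream), else *unannotated*.  The biotype
assigned to an annotated cluster is that of the overlapping gene with the
largest base-pair overlap; ties are broken by a fixed priority order that
favors small-RNA classes — miRNA genes are typically nested inside host
genes and a small-RNA assay should attribute the signal to them — then
alphabetically.

The index stores gene-level intervals plus exon/CDS sub-features from the
GTF/GFF; introns are derived as the gene interval minus the union of its
exons.  Biotype strings are taken verbatim from the annotation file
(``gene_biotype`` or ``gene_type`` attribute).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .metrics import UGR
from .quant import CountMatrix, cpm

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"

#: Tie-break priority for equal-overlap biotypes; lower rank wins.
BIOTYPE_PRIORITY = (
    "miRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "Mt_tRNA",
    "tRNA",
    "misc_RNA",
    "lincRNA",
    "lncRNA",
    "protein_coding",
)


def _priority(biotype: str) -> tuple[int, str]:
    try:
        return (BIOTYPE_PRIORITY.index(biotype), biotype)
    except ValueError:
        # pseudogene classes and anything else rank after the named classes
        rank = len(BIOTYPE_PRIORITY) if "pseudogene" in biotype else len(BIOTYPE_PRIORITY) + 1
        return (rank, biotype)


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    level: str  # gene | exon | CDS | intron


@dataclass
class AnnotationIndex:
    """Interval index over gene/exon/CDS/intron features of one gene model."""

    genes: dict[str, IntervalTree] = field(default_factory=dict)
    subfeatures: dict[str, IntervalTree] = field(default_factory=dict)
    n_missing_biotype: int = 0

    def add(self, feat: GeneFeature) -> None:
        trees = self.genes if feat.level == "gene" else self.subfeatures
        trees.setdefault(feat.chrom, IntervalTree()).addi(feat.start, feat.end, feat)

    def query_genes(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        tree = self.genes.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    @property
    def n_genes(self) -> int:
        return sum(len(t) for t in self.genes.values())


@dataclass(frozen=True)
class UGRAnnotation:
    ugr_id: str
    status: str  # annotated | unannotated
    biotype: str
    gene_ids: tuple[str, ...]
    overlap_bp: int
    overlap_fraction: float


def _attr(feature: gffutils.Feature, *names: str, default: str = "") -> str:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return default


def _filter_gtf_lines(path: str) -> tuple[str, int]:
    """Drop malformed GTF/GFF lines (wrong column count) before indexing."""
    kept: list[str] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                n_bad += 1
                logger.warning("%s:%d: malformed annotation line skipped", path, lineno)
                continue
            kept.append(line)
    return "".join(kept), n_bad


def build_index(gtf_path: str) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GTF/GFF file.

    Gene records are indexed directly; exon and CDS records are indexed as
    sub-features and the gaps between a gene's exons become derived introns.
    Features lacking a biotype attribute are indexed with biotype
    ``"unknown"`` and counted.
    """
    data, _ = _filter_gtf_lines(gtf_path)
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    index = AnnotationIndex()
    exons_by_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    gene_meta: dict[str, GeneFeature] = {}
    for feat in db.all_features():
        level = feat.featuretype
        if level not in ("gene", "exon", "CDS"):
            continue
        gene_id = _attr(feat, "gene_id", default=feat.id)
        biotype = _attr(feat, "gene_biotype", "gene_type")
        if not biotype:
            biotype = "unknown"
            index.n_missing_biotype += 1
        gf = GeneFeature(
            gene_id=gene_id,
            gene_name=_attr(feat, "gene_name", default=gene_id),
            biotype=biotype,
            chrom=feat.seqid,
            start=feat.start - 1,  # GTF is 1-based inclusive
            end=feat.end,
            strand=feat.strand or ".",
            level=level,
        )
        index.add(gf)
        if level == "gene":
            gene_meta[gene_id] = gf
        elif level == "exon":
            exons_by_gene.setdefault(gene_id, []).append(
                (gf.chrom, gf.start, gf.end, gf.strand)
            )
    # derive introns: gene span minus exon union
    for gene_id, exons in exons_by_gene.items():
        gene = gene_meta.get(gene_id)
        if gene is None:
            continue
        merged: list[list[int]] = []
        for _, s, e, _ in sorted(exons, key=lambda x: x[1]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        prev = gene.start
        for s, e in merged:
            if s > prev:
                index.add(
                    GeneFeature(gene_id, gene.gene_name, gene.biotype, gene.chrom,
                                prev, s, gene.strand, "intron")
                )
            prev = max(prev, e)
        if gene.end > prev:
            index.add(
                GeneFeature(gene_id, gene.gene_name, gene.biotype, gene.chrom,
                            prev, gene.end, gene.strand, "intron")
            )
    if index.n_missing_biotype:
        logger.warning(
            "%d feature(s) lacked a biotype attribute; labeled 'unknown'",
            index.n_missing_biotype,
        )
    return index


def annotate_ugr(ugr: UGR, index: AnnotationIndex, stranded: bool = False) -> UGRAnnotation:
    """Label one UGR as annotated/unannotated and assign its biotype."""
    hits = index.query_genes(ugr.chrom, ugr.start, ugr.end)
    if stranded:
        hits = [h for h in hits if h.strand == ugr.strand]
    if not hits:
        return UGRAnnotation(ugr.ugr_id, UNANNOTATED, UNANNOTATED, (), 0, 0.0)
    best: GeneFeature | None = None
    best_bp = -1
    overlaps: dict[str, int] = {}
    for h in hits:
        bp = min(ugr.end, h.end) - max(ugr.start, h.start)
        overlaps[h.gene_id] = max(overlaps.get(h.gene_id, 0), bp)
        if bp > best_bp or (bp == best_bp and best is not None
                            and _priority(h.biotype) < _priority(best.biotype)):
            best, best_bp = h, bp
    return UGRAnnotation(
        ugr_id=ugr.ugr_id,
        status="annotated",
        biotype=best.biotype,
        gene_ids=tuple(sorted(overlaps)),
        overlap_bp=best_bp,
        overlap_fraction=best_bp / ugr.length,
    )


def annotate_all(
    ugrs: Sequence[UGR], index: AnnotationIndex, stranded: bool = False
) -> list[UGRAnnotation]:
    return [annotate_ugr(u, index, stranded=stranded) for u in ugrs]


def annotation_table(annotations: Iterable[UGRAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "ugr_id": a.ugr_id,
            "status": a.status,
            "biotype": a.biotype,
            "gene_ids": ",".join(a.gene_ids),
            "overlap_bp": a.overlap_bp,
            "overlap_fraction": a.overlap_fraction,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows).set_index("ugr_id") if rows else pd.DataFrame()


def biotype_summary(
    ugrs: Sequence[UGR],
    annotations: Sequence[UGRAnnotation],
    counts: CountMatrix,
) -> pd.DataFrame:
    """Per-biotype table: locus count, molecule total, mean RPKM.

    *molecules* is the library-size-adjusted abundance: the sum over samples
    of counts-per-million, summed over the biotype's loci, so totals are
    conserved against the count matrix.  *mean_rpkm* additionally adjusts for
    locus length: RPKM = count / (length in kb x library size in millions),
    averaged over samples and loci.  An ``unannotated`` row is always
    present when unannotated loci exist, enabling rank-by-expression
    comparison of unannotated signal against known biotypes.
    """
    by_id = {u.ugr_id: u for u in ugrs}
    biotype_of = {a.ugr_id: a.biotype for a in annotations}
    cpm_mat = cpm(counts)
    lib_millions = counts.library_sizes / 1e6
    rows: dict[str, dict] = {}
    for ugr_id in counts.values.index:
        u = by_id.get(ugr_id)
        biotype = biotype_of.get(ugr_id, UNANNOTATED)
        row = rows.setdefault(
            biotype, {"biotype": biotype, "n_ugrs": 0, "molecules": 0.0, "_rpkm": []}
        )
        row["n_ugrs"] += 1
        row["molecules"] += float(cpm_mat.loc[ugr_id].sum())
        if u is not None:
            length_kb = u.length / 1e3
            rpkm = counts.values.loc[ugr_id] / (length_kb * lib_millions)
            row["_rpkm"].append(float(rpkm.mean()))
    out = []
    for row in rows.values():
        rpkms = row.pop("_rpkm")
        row["mean_rpkm"] = float(pd.Series(rpkms).mean()) if rpkms else float("nan")
        out.append(row)
    df = pd.DataFrame(out).set_index("biotype")
    return df.sort_values("molecules", ascending=False)
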