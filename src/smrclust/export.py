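"""Writers for the standard genomic output formats.

BED output is 0-based half-open; GFF3 output and the human-readable UGR ids
("chrom:start-end") are 1-based inclusive.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .metrics import UGR, metrics_table


def write_bed(ugrs: Sequence[UGR], path: str) -> None:
    """BED6: name is the UGR id, score the rounded weighted count."""
    with open(path, "w") as fh:
        for u in ugrs:
            fh.write(
                f"{u.chrom}\t{u.start}\t{u.end}\t{u.ugr_id}\t"
                f"{round(u.weighted_count)}\t{u.strand}\n"
            )


def write_gff3(ugrs: Sequence[UGR], path: str, source: str = "smrclust") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for u in ugrs:
            attrs = (
                f"ID={u.ugr_id};weighted_count={u.weighted_count:.3f};"
                f"complexity={u.complexity:.4f};peak_fraction={u.peak_fraction:.4f}"
            )
            fh.write(
                f"{u.chrom}\t{source}\tsmall_RNA_cluster\t{u.start + 1}\t{u.end}\t"
                f"{round(u.weighted_count)}\t{u.strand}\t.\t{attrs}\n"
            )


def write_metrics_tsv(ugrs: Sequence[UGR], path: str) -> None:
    metrics_table(ugrs).to_csv(path, sep="\t")


def write_consensus_fasta(ugrs: Iterable[UGR], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for u in ugrs:
            if not u.consensus:
                continue
            fh.write(f">{u.ugr_id}\n")
            for i in range(0, len(u.consensus), width):
                fh.write(u.consensus[i : i + width] + "\n")
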