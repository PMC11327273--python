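"""Synthetic small-RNA alignment data with planted cluster truth.

The generator emulates the statistical structure a small-RNA cluster caller
faces: read stacks that are peak-dominated (all reads sharing one start),
uniformly tiled (high complexity), or Gaussian-spread; cluster read counts
spanning orders of magnitude; loci inside and outside annotated genes;
duplicated loci producing multimapped reads; several samples with differing
library sizes; and a diffuse sub-threshold background.  It writes final
alignment records directly (no external aligner in the loop) plus truth
files recording, for every planted cluster, the interval and the analytic
metric values the caller is expected to recover.

Everything is driven by one integer seed; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
import yaml

DEFAULT_READ_LENGTH = 22  # miRNA-like
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ConfigurationError(ValueError):
    pass


@dataclass
class PlantedCluster:
    name: str
    chrom: str
    start: int
    end: int
    n_reads: int
    shape: str = "point"  # point | uniform | gaussian
    sigma: float = 10.0
    read_length: int = DEFAULT_READ_LENGTH
    strand: str = "+"
    multimap_copies: int = 1
    anchor_reads: int = 0
    annotated_as: str | None = None

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ConfigurationError(f"{self.name}: n_reads must be >= 1")
        if self.shape not in ("point", "uniform", "gaussian"):
            raise ConfigurationError(f"{self.name}: unknown shape {self.shape!r}")
        if self.end - self.start < self.read_length:
            raise ConfigurationError(
                f"{self.name}: read length {self.read_length} exceeds footprint "
                f"{self.end - self.start}"
            )
        if self.multimap_copies < 1:
            raise ConfigurationError(f"{self.name}: multimap_copies must be >= 1")


@dataclass
class SampleSpec:
    sample_id: str
    library_multiplier: float = 1.0
    condition: str = ""


@dataclass
class SimulationConfig:
    seed: int
    genome: dict[str, int]
    samples: list[SampleSpec]
    clusters: list[PlantedCluster]
    background_reads: int = 0
    substitution_rate: float = 0.0
    #: planted/decoy footprints are kept at least this far from background
    #: reads and from each other, so truth intervals are exact
    exclusion_margin: int = 150

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            seed=int(raw["seed"]),
            genome={str(k): int(v) for k, v in raw["genome"].items()},
            samples=[SampleSpec(**s) for s in raw["samples"]],
            clusters=[PlantedCluster(**c) for c in raw["clusters"]],
            background_reads=int(raw.get("background_reads", 0)),
            substitution_rate=float(raw.get("substitution_rate", 0.0)),
            exclusion_margin=int(raw.get("exclusion_margin", 150)),
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "seed": self.seed,
                    "genome": self.genome,
                    "samples": [dataclasses.asdict(s) for s in self.samples],
                    "clusters": [dataclasses.asdict(c) for c in self.clusters],
                    "background_reads": self.background_reads,
                    "substitution_rate": self.substitution_rate,
                    "exclusion_margin": self.exclusion_margin,
                },
                fh,
                sort_keys=False,
            )


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    #: cluster name -> list of (chrom, start) decoy loci holding a verbatim
    #: copy of the cluster's multimap region
    decoys: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    #: cluster name -> offset of the duplicated region within the footprint
    multimap_margin: dict[str, int] = field(default_factory=dict)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_footprints(config: SimulationConfig) -> None:
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for c in config.clusters:
        if c.chrom not in config.genome:
            raise ConfigurationError(f"{c.name}: unknown chromosome {c.chrom}")
        if c.end > config.genome[c.chrom]:
            raise ConfigurationError(f"{c.name}: footprint beyond chromosome end")
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end, c.name))
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ConfigurationError(
                    f"planted footprints {n1} and {n2} overlap on {chrom}"
                )


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate random chromosome sequences with duplicated decoy loci.

    Each cluster with ``multimap_copies = k > 1`` has its multimap region
    (the footprint minus an anchor margin when ``anchor_reads > 0``) copied
    verbatim to ``k - 1`` decoy loci placed outside every planted footprint.
    """
    for chrom, length in config.genome.items():
        if length < 1000:
            raise ConfigurationError(f"chromosome {chrom} shorter than 1 kb")
    _check_footprints(config)
    rng = np.random.default_rng(config.seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {
        chrom: rng.choice(bases, size=length)
        for chrom, length in config.genome.items()
    }

    margin = config.exclusion_margin
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.genome}
    for c in config.clusters:
        occupied[c.chrom].append((c.start - margin, c.end + margin))

    genome = SimulatedGenome(sequences={})
    for c in config.clusters:
        if c.multimap_copies <= 1:
            continue
        mm_margin = c.read_length if c.anchor_reads > 0 else 0
        genome.multimap_margin[c.name] = mm_margin
        src_start = c.start + mm_margin
        src = seqs[c.chrom][src_start : c.end]
        decoys = []
        for _ in range(c.multimap_copies - 1):
            pos = _place_decoy(rng, config, occupied, len(src), margin)
            chrom, start = pos
            seqs[chrom][start : start + len(src)] = src
            occupied[chrom].append((start - margin, start + len(src) + margin))
            decoys.append((chrom, start))
        genome.decoys[c.name] = decoys

    genome.sequences = {
        chrom: arr.tobytes().decode("ascii") for chrom, arr in seqs.items()
    }
    return genome


def _place_decoy(rng, config, occupied, length, margin, max_tries=1000):
    chroms = sorted(config.genome)
    for _ in range(max_tries):
        chrom = chroms[int(rng.integers(len(chroms)))]
        limit = config.genome[chrom] - length
        if limit <= 0:
            continue
        start = int(rng.integers(limit))
        if all(
            start + length + margin <= s or start >= e
            for s, e in occupied[chrom]
        ):
            return chrom, start
    raise ConfigurationError("could not place decoy locus; genome too crowded")


def write_genome_fasta(genome: SimulatedGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _planted_starts(cluster: PlantedCluster, n: int, mm_margin: int, rng) -> list[int]:
    """Start positions of n reads following the cluster's shape.

    Multimapped reads are confined to the duplicated region
    ``[start + mm_margin, end)``; anchor reads (handled separately) occupy
    the margin.  'uniform' tiles start positions round-robin so the start
    distribution is as even as arithmetic allows.
    """
    lo = cluster.start + mm_margin
    hi = cluster.end - cluster.read_length  # inclusive last start
    if hi < lo:
        raise ConfigurationError(f"{cluster.name}: read longer than usable footprint")
    if cluster.shape == "point":
        return [lo] * n
    if cluster.shape == "uniform":
        positions = list(range(lo, hi + 1))
        return [positions[i % len(positions)] for i in range(n)]
    draws = rng.normal((lo + hi) / 2.0, cluster.sigma, size=n)
    return [int(np.clip(round(d), lo, hi)) for d in draws]


def _entropy_complexity(starts: list[int], span: int) -> float:
    """Closed-form planted complexity: normalized entropy of start counts."""
    counts: dict[int, int] = {}
    for s in starts:
        counts[s] = counts.get(s, 0) + 1
    if span <= 1 or len(counts) == 1:
        return 0.0
    total = sum(counts.values())
    h = math.log(total) - sum(c * math.log(c) for c in counts.values()) / total
    return min(h / math.log(span), 1.0)


def _peak_fraction(starts: list[int], read_length: int) -> float:
    lo, hi = min(starts), max(starts) + read_length
    depth = np.zeros(hi - lo)
    for s in starts:
        depth[s - lo : s - lo + read_length] += 1
    peak = int(np.argmax(depth))
    covering = sum(1 for s in starts if s - lo <= peak < s - lo + read_length)
    return covering / len(starts)


@dataclass
class SimulationOutput:
    alignment_paths: dict[str, str]
    truth_bed: str
    truth_tsv: str
    genome_fasta: str
    annotation_gtf: str | None


def simulate_reads(
    config: SimulationConfig,
    genome: SimulatedGenome,
    out_dir: str,
    alignment_format: str = "bam",
) -> SimulationOutput:
    """Draw reads per planted cluster and write alignments plus truth files.

    Per sample, each cluster contributes ``round(n_reads x multiplier)``
    reads; multimapped reads are emitted at the true locus and at every
    decoy locus with correct hit-count (NH) tags.  Output alignments are
    coordinate-sorted BAM (indexed) or SAM.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_path = str(out / "genome.fa")
    write_genome_fasta(genome, fasta_path)

    chroms = sorted(config.genome)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": config.genome[c]} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}

    # one RNG per run; sample loops draw in a fixed order for determinism
    rng = np.random.default_rng(config.seed + 1)
    pooled_starts: dict[str, list[int]] = {c.name: [] for c in config.clusters}
    alignment_paths: dict[str, str] = {}

    for sample in config.samples:
        records = []
        serial = 0
        for cluster in config.clusters:
            n = max(1, round(cluster.n_reads * sample.library_multiplier))
            mm_margin = genome.multimap_margin.get(cluster.name, 0)
            n_anchor = min(cluster.anchor_reads, n) if cluster.multimap_copies > 1 else 0
            anchor_starts = [
                cluster.start + (i % max(mm_margin, 1))
                for i in range(n_anchor)
            ] if mm_margin else []
            body_starts = _planted_starts(cluster, n - n_anchor, mm_margin, rng)
            starts = anchor_starts + body_starts
            pooled_starts[cluster.name].extend(starts)
            for s in starts:
                serial += 1
                is_anchor = s < cluster.start + mm_margin
                sites = [(cluster.chrom, s)]
                if cluster.multimap_copies > 1 and not is_anchor:
                    offset = s - (cluster.start + mm_margin)
                    sites += [
                        (dchrom, dstart + offset)
                        for dchrom, dstart in genome.decoys[cluster.name]
                    ]
                records.extend(
                    _make_records(
                        f"{sample.sample_id}_{cluster.name}_{serial}",
                        sites,
                        cluster.read_length,
                        cluster.strand,
                        genome,
                        header,
                        tid,
                        rng,
                        config.substitution_rate,
                    )
                )
        records.extend(
            _background_records(config, genome, sample, header, tid, rng)
        )
        records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
        path = _write_alignments(records, out, sample.sample_id, header, alignment_format)
        alignment_paths[sample.sample_id] = path

    truth_bed = str(out / "truth.bed")
    truth_tsv = str(out / "truth.tsv")
    _write_truth(config, genome, pooled_starts, truth_bed, truth_tsv)
    gtf = _write_annotation(config, out)
    return SimulationOutput(alignment_paths, truth_bed, truth_tsv, fasta_path, gtf)


def _make_records(
    name, sites, read_length, strand, genome, header, tid, rng, sub_rate
):
    chrom0, s0 = sites[0]
    seq = genome.sequences[chrom0][s0 : s0 + read_length]
    if sub_rate > 0:
        seq = list(seq)
        for i in range(len(seq)):
            if rng.random() < sub_rate:
                seq[i] = "ACGT"[int(rng.integers(4))]
        seq = "".join(seq)
    records = []
    for i, (chrom, start) in enumerate(sites):
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.query_sequence = seq
        rec.query_qualities = pysam.qualitystring_to_array("I" * read_length)
        rec.reference_id = tid[chrom]
        rec.reference_start = start
        rec.cigarstring = f"{read_length}M"
        rec.mapping_quality = 255 if len(sites) == 1 else 0
        rec.flag = (16 if strand == "-" else 0) | (256 if i > 0 else 0)
        rec.set_tag("NH", len(sites))
        records.append(rec)
    return records


def _background_records(config, genome, sample, header, tid, rng):
    n = round(config.background_reads * sample.library_multiplier)
    if n == 0:
        return []
    margin = config.exclusion_margin
    read_length = DEFAULT_READ_LENGTH
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in config.genome}
    for c in config.clusters:
        forbidden[c.chrom].append((c.start - margin - read_length, c.end + margin))
    for decoys in genome.decoys.values():
        for chrom, start in decoys:
            forbidden[chrom].append((start - margin - read_length, start + margin + 10_000))
    chroms = sorted(config.genome)
    records = []
    placed = 0
    tries = 0
    while placed < n and tries < n * 100:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        limit = config.genome[chrom] - read_length
        start = int(rng.integers(limit))
        if any(s <= start < e for s, e in forbidden[chrom]):
            continue
        placed += 1
        records.extend(
            _make_records(
                f"{sample.sample_id}_bg_{placed}",
                [(chrom, start)],
                read_length,
                "+",
                genome,
                header,
                tid,
                rng,
                config.substitution_rate,
            )
        )
    return records


def _write_alignments(records, out, sample_id, header, fmt):
    if fmt == "sam":
        path = str(out / f"{sample_id}.sam")
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for rec in records:
                fh.write(rec)
    else:
        path = str(out / f"{sample_id}.bam")
        with pysam.AlignmentFile(path, "wb", header=header) as fh:
            for rec in records:
                fh.write(rec)
        pysam.index(path)
    return path


def _write_truth(config, genome, pooled_starts, bed_path, tsv_path):
    # expect_called marks clusters guaranteed to survive the default
    # 100-read threshold when all samples are pooled; multimapped clusters
    # are excluded because their retained weight at the true locus depends
    # on the rescue outcome.
    from .caller import DEFAULT_MIN_READS

    rows = []
    for c in config.clusters:
        starts = pooled_starts[c.name]
        lo, hi = min(starts), max(starts) + c.read_length
        rows.append(
            {
                "name": c.name,
                "chrom": c.chrom,
                "start": lo,
                "end": hi,
                "strand": c.strand,
                "shape": c.shape,
                "n_reads_planted": len(starts),
                "multimap_copies": c.multimap_copies,
                "anchor_reads": c.anchor_reads,
                "annotated_as": c.annotated_as or "",
                "expect_called": len(starts) >= DEFAULT_MIN_READS
                and c.multimap_copies == 1,
                "expected_complexity": _entropy_complexity(starts, hi - lo),
                "expected_peak_fraction": _peak_fraction(starts, c.read_length),
            }
        )
    rows.sort(key=lambda r: (r["chrom"], r["start"]))
    with open(bed_path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['name']}\t"
                f"{r['n_reads_planted']}\t{r['strand']}\n"
            )
    cols = list(rows[0]) if rows else []
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")


def _write_annotation(config, out: Path) -> str | None:
    annotated = [c for c in config.clusters if c.annotated_as]
    if not annotated:
        return None
    path = str(out / "annotation.gtf")
    with open(path, "w") as fh:
        for c in annotated:
            attrs = (
                f'gene_id "{c.name}"; gene_name "{c.name}"; '
                f'gene_biotype "{c.annotated_as}";'
            )
            for level in ("gene", "exon"):
                fh.write(
                    f"{c.chrom}\tsim\t{level}\t{c.start + 1}\t{c.end}\t.\t"
                    f"{c.strand}\t.\t{attrs}\n"
                )
    return path


def write_fastq(
    config: SimulationConfig,
    genome: SimulatedGenome,
    path: str,
    head_bases: int = 3,
    adapter: str = "AAAAAAAAAA",
) -> None:
    """Emit raw (untrimmed) reads for full-path tests through read trimming.

    Each read is the sequenced form (reverse-complemented for minus-strand
    clusters) flanked by a random leading triad and the 3' adapter,
    emulating template-switching library chemistry.  One FASTQ pools all
    samples.
    """
    rng = np.random.default_rng(config.seed + 2)
    with open(path, "w") as fh:
        serial = 0
        for sample in config.samples:
            for cluster in config.clusters:
                n = max(1, round(cluster.n_reads * sample.library_multiplier))
                mm_margin = genome.multimap_margin.get(cluster.name, 0)
                for s in _planted_starts(cluster, n, mm_margin, rng):
                    serial += 1
                    insert = genome.sequences[cluster.chrom][s : s + cluster.read_length]
                    if cluster.strand == "-":
                        insert = _revcomp(insert)
                    head = "".join(
                        "ACGT"[int(rng.integers(4))] for _ in range(head_bases)
                    )
                    seq = head + insert + adapter
                    fh.write(f"@sim_{serial}\n{seq}\n+\n{'I' * len(seq)}\n")
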