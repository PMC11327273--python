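# Methods

## Model and assumptions

`smrclust` treats the small-RNA transcriptome as a set of accumulation loci
("small read clusters", smRCs/UGRs) to be discovered directly from aligned
read positions, without reference to annotation. The underlying assumptions
are those of short-read small-RNA sequencing: reads are short (15–75 nt,
typically ~22 nt), essentially ungapped against the reference, and pile up
in stacks at the loci that produce them; duplicate read positions are
biological signal, not PCR artifacts to remove. Alignment itself is
upstream: any aligner that emits SAM/BAM with per-read hit counts (`NH`
tag) or one record per site will do.

## Adapter trimming

The trimmer reproduces the preparation of reads from template-switching
small-RNA library chemistry: remove the first `head_trim` bases (default 3,
the non-templated 5′ triad), locate the 3′ adapter (default the `A₁₀`
homopolymer left by oligo-dT priming plus adapter) and cut it with
everything 3′ of it, then discard reads shorter than `min_length`
(default 15 nt).

Adapter matching uses the standard 3′-adapter convention: a candidate
occurrence at offset *i* spans `L = min(|adapter|, |read| − i)` adapter
bases (so partial occurrences are only possible hanging off the 3′ end) and
is valid when `L ≥ min_overlap` (default 3) and its mismatch count is at
most `⌊0.1·L⌋`. `N` never matches. Among valid occurrences the one with the
most matching bases wins, ties prefer fewer errors, then the leftmost
offset — so an exact full-length hit beats an earlier near-miss, which is
the behavior users of the common trimming tools expect. Indels are not
modeled: for a homopolymer adapter an indel is indistinguishable from a
mismatch plus shift. Quality strings are truncated in lockstep and never
modified.

## Multimap rescue

Discarding multimapped reads biases cluster discovery against duplicated
loci (rRNA fragments, miRNA families, repeats); counting every site
inflates them. The rescue is a deliberately simple single pass: reads with
more than `max_sites` (default 15) reported sites are dropped as
unmappable; otherwise each site receives weight proportional to the mean
unique-read depth over its footprint, with an even `1/k` split when no site
has unique support. Sites receiving exactly zero mass are dropped. An
iterative EM reallocation would also let multimapped mass attract further
multimapped mass; the single-pass scheme was chosen because it is
deterministic, order-independent, and transparent — the unique reads are
the only arbiter. `rescue_window` (default 0 bp) can widen the depth
window when unique anchors sit adjacent to, rather than under, the
multimapped stack.

`max_sites` is exposed because two conventions are in circulation for this
assay family (10 for gene-level quantification, 15 for cluster discovery);
15 is the default for cluster calling.

## Cluster calling

Calling is single-linkage gap clustering on weighted reads sorted by start:
a read joins the open cluster while `next.start − running_max_end <
min_gap`; overlapping or book-ended reads always join. This is equivalent
to sliding a window of width `min_gap` over read starts, and guarantees
every pair of reported clusters is separated by ≥ `min_gap`. Clusters whose
weighted count is below `min_reads` are discarded — never merged into a
neighbour, so reported mass is bounded by input mass.

Defaults: `min_gap = 75` bp (the typical trimmed read length for this
chemistry — two stacks closer than one read length apart are not
resolvable as distinct loci) and `min_reads = 100` (the minimum coverage at
which annotated small-RNA loci are reliably detected; also a pragmatic
floor for calling a locus expressed). The threshold applies to the
*weighted* count by default (`count_mode="reads"` counts each retained read
once, for comparison). Cluster lengths are reported, never clipped.

Clustering is unstranded by default: locus discovery by accumulation does
not require strand separation even for strand-sensitive libraries, and the
unstranded locus set is a superset. `--stranded` clusters each strand
independently for users who want strand-resolved loci.

Two multi-sample modes exist. The default pools all samples' weighted reads
to define one shared locus set (one "average de novo assembled landscape"),
then quantifies each sample against it — this is what a single count matrix
across samples implies. `--per-sample` calls per sample and unions
overlapping intervals; characterization metrics are computed from the
pooled reads in both modes.

## Cluster metrics

*Complexity* is the Shannon entropy of the weighted read **start-position**
distribution, normalized by `ln(span)`:
`C = −Σ_b p_b ln p_b / ln(end − start)`, defined as 0 when the span is ≤ 1
or all reads share one start. Start-position entropy (rather than per-base
depth entropy) is used because it pins both endpoints exactly: a single
read stack scores 0, and equal-mass starts at every base score exactly 1.
The entropy is computed as `ln W − (Σ w ln w)/W` so the uniform unit-weight
case hits 1.0 without floating-point residue. The log base cancels in the
ratio. Complexity is invariant under uniform weight rescaling and
non-decreasing when mass moves from the modal start to an empty start.

*Peak* statistics are defined on weighted per-base depth: the peak is the
maximal-depth base (ties → leftmost), peak coverage the summed weight of
reads covering it, peak fraction that coverage over the cluster total
(1 iff every member covers the modal base).

*Consensus* is computed over the peak-supporting reads only, spanning their
joint footprint: per column, the weighted-majority base among reads that
align a base there (reads are projected onto reference coordinates at load
time; deletion columns cast no vote, insertions are dropped by the
projection), ties broken A < C < G < T, uncovered columns emitting `N`.
Ungapped alignments are the expected case for small-RNA aligners.

*Group comparison* (`compare_properties`) runs a two-sided Wilcoxon
rank-sum (Mann–Whitney) test per property with Benjamini–Hochberg
adjustment across properties. The exact null distribution is used when the
pooled data are tie-free and group sizes are ≤ 25, the normal approximation
otherwise; constant pooled data are flagged degenerate with p = 1.

## Annotation

A gene model (GTF/GFF, Ensembl/GENCODE dialects) is indexed at gene level
with exon/CDS sub-features; introns are derived as gene minus exon-union.
Any ≥ 1 bp overlap with a gene makes a cluster "annotated" — no fraction
threshold is imposed, but the overlap fraction is reported so users can
re-threshold. The biotype of the largest-overlap gene is assigned;
equal-overlap ties fall to a fixed priority favoring small-RNA classes
(miRNA > snoRNA > snRNA > rRNA > tRNA classes > lincRNA > protein_coding >
pseudogene classes > other, then alphabetical), because miRNA genes are
typically nested inside host genes and a small-RNA assay should attribute
the signal to the small RNA. Annotation is strand-agnostic by default,
consistent with unstranded calling. Features without a biotype attribute
are indexed as `unknown`; malformed annotation lines are skipped with a
counted warning.

The per-biotype summary reports locus counts, "molecules" (the sum over
samples and loci of CPM, i.e. library-size-adjusted abundance — defined
this way so biotype totals are conserved against the count matrix), and
mean RPKM (`count / (length_kb × library_size_millions)`) to compare
expression across loci of different lengths, including an `unannotated`
row for rank-by-expression comparisons.

## Quantification

Each sample's weighted reads are counted against the unified,
non-overlapping cluster intervals. A read is assigned to the single
interval it overlaps most (ties → leftmost) and never split, keeping counts
interpretable and column sums bounded by library sizes; library size is the
sample's total retained read weight. CPM is `1e6 · count / library_size`;
log2-CPM uses the voom-style transform `log2((count + 0.5) /
(libsize + 1) · 1e6)` with the pseudo-count recorded in the output. The
expression filter keeps a locus when more than `cpm_threshold` CPM
(default 10, strict inequality) is reached in at least `min_samples`
samples (default 1), evaluated within at least one phenotype group when
groups are given. Heavier modeling — TMM normalization, limma/voom
differential expression, PCA — is deliberately not reimplemented; the
exported counts + library-size TSVs are the layout those packages ingest.

## Synthetic data

The simulator generates what the caller assumes: random ~uniform-GC
chromosomes; planted clusters with point (single shared start), uniform
(round-robin tiled starts, so the start distribution is as even as
arithmetic allows and the planted complexity has a closed form) and
Gaussian shapes; read counts from ~10² to ~10⁴; several samples with
library-size multipliers; a scattered sub-threshold background kept at
least `exclusion_margin` (default 150 bp) away from planted footprints so
truth intervals are exact; and multimapping, created by copying a cluster's
footprint sequence verbatim to decoy loci and emitting each such read at
all sites with correct `NH` tags. When anchor (unique) reads are requested
for a multimapped cluster, the decoys copy the footprint minus a
read-length margin and the anchors start inside that margin, so their
uniqueness is consistent at sequence level. Alignment records are written
directly (coordinate-sorted BAM or SAM) — no aligner in the loop — and an
optional FASTQ mode emits raw reads (5′ triad + insert + adapter) for
full-path tests through the trimmer. Truth files record each planted
cluster's exact expected interval and analytic complexity / peak fraction
computed in closed form from the planted start counts.

What the simulator does **not** emulate: sequencing-quality models,
ligation/position bias, genomic repeat structure beyond the planted decoys,
chimeric or spliced reads, and contaminating non-host reads. Passing
end-to-end tests therefore demonstrate correctness of the pipeline's logic
under its own model, not robustness to every artifact of real libraries;
upstream filtering (e.g. of microbial reads) is assumed done before input.

Problem sizes in the test suite (tens of kb of genome, ~10³–10⁴ reads,
hundreds of oracle instances) were chosen as the smallest scales at which
every behavior of interest — threshold and gap boundaries, rescue, shape
recovery — is exercised with exact expectations.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally and in BED; human-readable
  ids (`chrom:start-end`) and GFF3 are 1-based inclusive.
- Weight sums are conserved to ≤ 1e-6 per million reads; cluster threshold
  comparisons use `≥` on the accumulated float sum.
- Ties: peak base → leftmost; consensus base → A < C < G < T; read-to-UGR
  assignment → larger overlap, then leftmost; biotype → larger overlap,
  then the priority list, then alphabetical.
- Degenerate inputs: empty clusters are rejected; span-1 clusters have
  complexity 0; sequence-less peak reads yield an empty consensus with a
  warning; constant profiles yield NaN Spearman rho with a warning; zero
  retained reads yield an all-zero matrix column with a warning.
- Determinism: nothing but the simulator draws random numbers, and it is
  fully determined by the config seed; reruns are byte-identical.

## Known limitations

- Rescue is single-pass; loci whose support is exclusively multimapped
  (no unique anchors anywhere) fall back to even splitting and may dilute
  below threshold across decoys.
- No sub-cluster peak deconvolution: one cluster may contain several peaks
  closer than `min_gap`; only the dominant peak is characterized.
- The whole alignment file is grouped in memory; appropriate for small-RNA
  libraries (tens of millions of short records), not whole-genome DNA-seq.
- Consensus assumes ungapped alignments; reference-skip (`N`) CIGAR records
  are skipped at load with a counted warning.
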