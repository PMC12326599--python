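# Methods

This note records the models, conventions and design choices behind
telokit, and what its synthetic validation does and does not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open, matching SAM/BAM and the
UCSC table browser; GTF (1-based inclusive) and RepeatMasker `.out`
(1-based inclusive, strand `C` = minus) are converted at the file
boundary only. The repeat-class universe treated as TE is
{LINE, SINE, LTR, DNA, RC, Retroposon}; a trailing `?` on a repClass is
stripped before matching, `Unknown` and non-TE repeats (simple repeats,
low-complexity, tRNA/rRNA and similar) are excluded, and RC
(rolling-circle/Helitron) elements are retained but folded into DNA in
all superfamily summaries, the common convention. Writers are
byte-deterministic (GTF attribute order fixed; gzip members written with
mtime 0) so reruns can be compared by checksum.

## Genome masks and read classification

Overlap queries use per-chromosome boolean vectors (one bit per base) for
the four annotation layers: all TEs, intergenic TEs, intragenic TEs, and
nonTE gene exons. A repeat is intragenic iff it overlaps any gene
transcript span by ≥ 1 bp — element-level labeling against full spans,
so intronic TEs are intragenic; exon-level overlap is handled by the
separate exon mask. Masks are unstranded; strand is honored only in
splice-motif extraction.

A read's footprint is its reference-consuming CIGAR blocks: M/=/X and D
advance the reference inside a block (a deletion bridges, it never
splits), N splits blocks, I/S/P consume nothing, and H flags the record
for exclusion. "Aligned length" is the summed block width, so deleted
reference bases count and skipped introns do not — overlap is measured in
reference space under the alignment footprint. Uniquely mapped is
operationalized as primary + MAPQ ≥ 30 + no hard clips; hard-clipped
records are excluded because the aligner emits them when re-aligning
quality-compromised reads.

Classification precedence is 1 → 3 → 2 → 4 with these exact rules:
category 1 requires exon_bp = 0, intergenic-TE overlap > 0 **and**
intragenic-TE overlap = 0 (reads overlapping only an intronic TE fall to
category 4); category 3 (fusion) outranks category 2 because a read
spanning a gene and an intergenic TE is a fusion candidate regardless of
its intragenic fraction; the 80% rule of category 2 is strict (> 0.8, a
read at exactly 0.8 falls through). Duplicate input records are counted
twice, never deduplicated. Whether "overlapping a nonTE gene" means exon
or gene-body overlap was an open choice; the exon mask is used because it
is the mask the pipeline constructs.

## TE-derived transcript annotation

Composition percentages are relative to **mature length** (sum of exon
widths), not genomic span; intronic repeat bases never count, and copies
of the same subfamily are merged over the union of their exonic bases (no
double counting). Names are the gene label plus subfamilies in
(−percentage, name) order, sanitized to `[A-Za-z0-9.-]`. Superfamily is
the class with maximal summed exonic bp; exact ties break by the fixed
order LINE > SINE > LTR > DNA > Retroposon. The transcription end site is
reported 1-based: last exon end on +, first exon start + 1 on −. The
external assembler is documented only (StringTie2 with
`-L -G -v -p 12 -j 1 -g 0 -f 0.01 -l STRG -m 50 -t -c 1.5 -s 1.5`); the
annotator consumes any GTF, so no test requires it.

## Splice motifs

Donor windows are 3 exonic + 6 intronic bases, acceptor windows
6 intronic + 3 exonic, read 5′→3′ on the transcript strand
(minus-strand windows mirrored and reverse-complemented). The widths are
a package choice made to bracket the GT/AG dinucleotides with context;
they are exposed as options. Counts ignore N; the information transform
is IC(b, i) = p(b, i)·(2 − H_i) with 0·log 0 = 0, no pseudocounts, and
all-zero columns stay zero rather than erroring — the transform is
descriptive, not inferential. Both the entropy-derived probability layer
and the IC layer are emitted, since sequence-logo conventions sometimes
conflate the two.

## Single-cell quantification

Reconciliation is conservative and strand-agnostic: a TE transcript with
≥ 1 bp exonic overlap against any nonTE gene exon is removed before
quantification, so shared regions always count toward the gene.
Assignment within the transcript layer: candidates are collected by
block–exon overlap; any nonTE candidate drops all TE candidates; the
surviving gene id must be unique (else ambiguous, reported in stats);
the isoform is the best-overlap transcript, with exact ties counting the
gene only. The repeat layer is independent: a read counts toward every
element it overlaps by ≥ 1 bp, and that matrix is written to a separate
directory so the transcript matrix stays shape-compatible with standard
tools. Counting is one increment per distinct (barcode, feature, UMI)
triple — exact-string UMI collapse, no 1-mismatch merging (an extension
point). Reads lacking CB or UB, off-whitelist barcodes, ambiguous and
unassigned reads are all tallied; the stats partition the total record
count exactly.

## Cohort statistics

Normalization scales each cell to the median of per-cell totals then
applies ln(1 + x), matching the default of the standard
normalize-total/log1p preprocessing (cross-checked against scanpy in the
test suite); zero-total cells are left at zero with a warning. The
per-cell TE fraction defaults to the detected-features definition
(# nonzero TE features / # nonzero features) with a UMI-share mode
selectable. Tissue TE sets threshold the **sum of log1p-normalized
values** at ≥ 100 by default (raw-sum selectable), and UpSet-style
intersection sizes are exact set-partition counts. Marker detection is a
one-vs-rest Wilcoxon rank-sum per cell type using the tie-corrected
normal approximation (z = (R − μ)/σ, μ = n₁(n₁+n₂+1)/2, σ² tie-adjusted),
two-sided p, Benjamini–Hochberg within each cell type, TE rows selected
by "STRG." in the feature id at adjusted p < 0.05. Wilcoxon was chosen
as the primary test; a t-test would be the main alternative for these
contrasts and gives the same qualitative answers on the synthetic
fixtures.

## Synthetic fixtures: what they show

The generator builds a 2 × 100 kb genome with 20 three-exon genes
(GT..AG introns forced into the sequence), one TE embedded in each middle
exon and each first intron, and ~160 intergenic TEs drawn from a
subfamily catalog with genome-like class proportions (SINE 0.39,
LINE 0.32, LTR 0.15, DNA 0.10, Retroposon 0.04). Long reads are
*constructed* to satisfy one category definition each — including reads
at exactly the 0.80 boundary, low-MAPQ and hard-clipped decoys, and
CIGARs exercising N/I/D/S/H — and every construction is re-verified
against a per-base oracle before the read is emitted, so fixture truth
cannot silently drift. Barcoded reads emit each Poisson-drawn molecule
as 1–3 PCR duplicates sharing CB/UB. Problem sizes (100 kb chromosomes,
~1,000 reads, tens of cells, 150-cell marker matrices, 20 power and
50–100 null replicates) were chosen as the smallest scales at which every
decision rule and boundary case is exercised.

What passing these tests does **not** show: robustness to alignment
error, soft-clip-induced footprint truncation, repeat-family sequence
homology (toy TEs are random sequence at annotated positions), barcode
sequencing errors, or the multiple-testing behavior at transcriptome
scale (tens of features, not tens of thousands). The statistics are
exact-arithmetic checks and calibration checks at toy scale, not
re-estimates of any cohort-level biological quantity.

## Known limitations

- Micro-exons and other aligner-sensitive structures are outside scope:
  the package consumes alignments as given.
- Chimeric/supplementary-alignment fusion detection is not attempted;
  fusions are detected only via contiguous spliced alignments.
- UMI collapse is exact-match; no error-aware merging.
- The repeat-element count layer counts a read toward every overlapped
  element (no fractional allocation).
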