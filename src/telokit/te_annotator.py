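"""TE-derived transcript annotation: composition, naming, summaries.

Takes the transcripts an external assembler (StringTie2) produced from the
merged category-1..3 reads, works out which RepeatMasker subfamilies each
transcript's exons overlap, names the transcript by its gene label plus
the subfamilies in decreasing order of exonic overlap percentage, assigns
a superfamily by greatest overlap, and summarizes the annotation
(transcript counts, isoforms-per-gene histogram, superfamily shares).

The assembler itself is an external stage; the documented invocation is
STRINGTIE2_ARGS below and nothing here shells out to it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .formats_io import (
    GenomicInterval,
    RepeatElement,
    Transcript,
    group_by_gene,
)

__all__ = [
    "TEComposition",
    "TETranscript",
    "AnnotationSummary",
    "RepeatIndex",
    "STRINGTIE2_ARGS",
    "SUPERFAMILIES",
    "build_guide_annotation",
    "te_composition",
    "name_transcript",
    "assign_superfamily",
    "annotate_transcripts",
    "summarize_annotation",
    "transcript_metrics",
]

#: Assembler parameters used to build the annotation (documented, external).
STRINGTIE2_ARGS = ("-L -G -v -p 12 -j 1 -g 0 -f 0.01 -l STRG -m 50 -t "
                   "-c 1.5 -s 1.5")

#: The five reported superfamilies; RC (Helitron) is folded into DNA.
SUPERFAMILIES = ("LINE", "SINE", "LTR", "DNA", "Retroposon")
_TIE_ORDER = {cls: i for i, cls in enumerate(SUPERFAMILIES)}


@dataclass
class TEComposition:
    """Ranked subfamily overlaps of one transcript.

    entries: list of (subfamily, overlap_bp, overlap_pct), deduplicated by
    subfamily (union of exonic bases over all copies) and sorted by
    (-overlap_pct, subfamily).  Percentages are relative to the mature
    (exonic) transcript length.
    """

    entries: list = field(default_factory=list)
    class_bp: dict = field(default_factory=dict)  # superfamily -> bp

    def __bool__(self) -> bool:
        return bool(self.entries)

    @property
    def subfamilies(self) -> list:
        return [name for name, _, _ in self.entries]


@dataclass
class TETranscript:
    transcript: Transcript
    composition: TEComposition
    superfamily: str
    display_name: str

    @property
    def gene_id(self) -> str:
        return self.transcript.gene_id

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


@dataclass
class AnnotationSummary:
    n_transcripts: int
    n_genes: int
    isoform_histogram: dict  # isoform count -> number of genes
    superfamily_counts: dict
    superfamily_proportions: dict


class RepeatIndex:
    """Interval index over repeat elements, one tree per chromosome."""

    def __init__(self, repeats) -> None:
        self.trees: dict = {}
        for rep in repeats:
            self.trees.setdefault(rep.interval.chrom, IntervalTree()).addi(
                rep.interval.start, rep.interval.end, rep)

    def overlapping(self, iv: GenomicInterval):
        tree = self.trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]


def build_guide_annotation(genes, repeats, sizes: dict | None = None) -> list:
    """Gene transcripts plus one single-exon transcript per repeat element.

    The result guides the external assembly: known gene structures plus
    every TE locus as a candidate single-exon transcript (gene_id and
    transcript_id both the element_id).  ``repeats`` must be
    te_only-filtered; with ``sizes`` given, out-of-bounds repeats error.
    """
    out = list(genes)
    for rep in repeats:
        iv = rep.interval
        if sizes is not None:
            if iv.chrom not in sizes:
                raise KeyError(f"repeat on unknown chromosome {iv.chrom}")
            if iv.end > sizes[iv.chrom]:
                raise ValueError(
                    f"repeat {rep.element_id} exceeds {iv.chrom} length")
        out.append(Transcript(
            transcript_id=rep.element_id, gene_id=rep.element_id,
            interval=iv, exons=[iv], source_kind="TE_derived",
        ))
    return out


def _merged_len(intervals) -> int:
    """Union length of (start, end) pairs."""
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def te_composition(transcript: Transcript, index: RepeatIndex) -> TEComposition:
    """Exon-wise subfamily overlaps of one transcript.

    Intronic repeat bases never count.  Copies of the same subfamily are
    merged (union of exonic bases, no double counting); per-subfamily
    percentages are overlap_bp / mature_length * 100.  An empty
    composition signals "not TE-derived" to the caller.
    """
    pieces: dict = {}   # subfamily -> list of (start, end) exonic overlaps
    classes: dict = {}  # subfamily -> superfamily
    for ex in transcript.exons:
        for rep in index.overlapping(ex):
            s = max(ex.start, rep.interval.start)
            e = min(ex.end, rep.interval.end)
            if s < e:
                pieces.setdefault(rep.subfamily, []).append((s, e))
                classes[rep.subfamily] = rep.superfamily
    mature = transcript.mature_length
    entries = []
    class_bp: dict = {}
    for sub, ivs in pieces.items():
        bp = _merged_len(ivs)
        entries.append((sub, bp, 100.0 * bp / mature))
        cls = "DNA" if classes[sub] == "RC" else classes[sub]
        class_bp[cls] = class_bp.get(cls, 0) + bp
    entries.sort(key=lambda t: (-t[2], t[0]))
    return TEComposition(entries=entries, class_bp=class_bp)


_SAFE_CHARS = re.compile(r"[^A-Za-z0-9.-]")


def name_transcript(gene_label: str, composition: TEComposition) -> str:
    """``<gene_label>_<sub1>_<sub2>...`` in composition order.

    Subfamily names are sanitized (anything outside [A-Za-z0-9.-] becomes
    "-") so the name survives GTF attributes and file paths.
    """
    if not composition:
        raise ValueError("cannot name a transcript with empty TE composition")
    parts = [gene_label]
    parts += [_SAFE_CHARS.sub("-", sub) for sub in composition.subfamilies]
    return "_".join(parts)


def assign_superfamily(composition: TEComposition) -> str:
    """Superfamily with the greatest summed exonic overlap.

    RC was already folded into DNA when the composition was built; ties
    break by the fixed order LINE > SINE > LTR > DNA > Retroposon.
    """
    if not composition.class_bp:
        raise ValueError("empty composition has no superfamily")
    return min(
        composition.class_bp.items(),
        key=lambda kv: (-kv[1], _TIE_ORDER.get(kv[0], len(_TIE_ORDER))),
    )[0]


def annotate_transcripts(assembled, repeats) -> list:
    """Full annotation pass over an assembler's transcripts.

    Transcripts with no exonic TE overlap are dropped (they are not
    TE-derived); survivors get composition, superfamily, display name and
    the GTF attributes te_subfamilies / te_superfamily / mature_length.
    """
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats)
    out = []
    for tx in assembled:
        comp = te_composition(tx, index)
        if not comp:
            continue
        name = name_transcript(tx.gene_id, comp)
        sup = assign_superfamily(comp)
        tx = Transcript(
            transcript_id=tx.transcript_id, gene_id=tx.gene_id,
            interval=tx.interval, exons=list(tx.exons),
            source_kind="TE_derived",
            attributes={
                **tx.attributes,
                "te_subfamilies": ",".join(comp.subfamilies),
                "te_superfamily": sup,
                "mature_length": str(tx.mature_length),
            },
        )
        out.append(TETranscript(transcript=tx, composition=comp,
                                superfamily=sup, display_name=name))
    return out


def summarize_annotation(te_transcripts) -> AnnotationSummary:
    """Gene-level summary: isoform histogram and superfamily composition.

    A gene's superfamily is taken from its first transcript (all isoforms
    of one assembled gene share the same locus, hence class).
    """
    genes = group_by_gene(
        tt.transcript for tt in te_transcripts)
    histogram: dict = {}
    counts = {cls: 0 for cls in SUPERFAMILIES}
    sup_by_gene: dict = {}
    for tt in te_transcripts:
        sup_by_gene.setdefault(tt.gene_id, tt.superfamily)
    for gid, txs in genes.items():
        histogram[len(txs)] = histogram.get(len(txs), 0) + 1
        counts[sup_by_gene[gid]] = counts.get(sup_by_gene[gid], 0) + 1
    n_genes = len(genes)
    props = {cls: (counts[cls] / n_genes if n_genes else 0.0)
             for cls in counts}
    return AnnotationSummary(
        n_transcripts=sum(len(v) for v in genes.values()),
        n_genes=n_genes,
        isoform_histogram=dict(sorted(histogram.items())),
        superfamily_counts=counts,
        superfamily_proportions=props,
    )


def transcript_metrics(te_transcript: TETranscript) -> dict:
    """Mature length, genomic span and 1-based transcription end site."""
    tx = te_transcript.transcript
    if tx.strand == "-":
        tes = tx.exons[0].start + 1
    else:
        tes = tx.exons[-1].end
    return {
        "mature_length": tx.mature_length,
        "genomic_span": len(tx.interval),
        "tes_coordinate": tes,
    }
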