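"""Filtering and four-way classification of TE-overlapping long reads.

A read that survives the uniqueness filters (primary alignment, MAPQ >= 30,
no hard clips) and touches at least one TE base is assigned to exactly one
category:

1. intergenic   — overlaps an intergenic TE only; no exon, no intragenic TE
3. fusion       — overlaps a nonTE gene exon AND an intergenic TE
2. intragenic   — overlaps a nonTE gene exon and an intragenic TE covering
                  strictly more than 80% of the aligned length
4. other        — every remaining TE-overlapping read

Precedence is 1 -> 3 -> 2 -> 4: fusion outranks intragenic because a read
spanning a gene and an intergenic TE is a fusion candidate regardless of
its intragenic TE fraction.  Categories 1-3 feed transcript assembly;
category 4 is excluded as ambiguous.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field

import pysam

from .formats_io import GenomicInterval
from .genome_mask import MaskSet, overlap_bp

__all__ = [
    "AlignedRead",
    "ReadClassification",
    "CategoryReport",
    "blocks_from_cigar",
    "blocks_from_cigartuples",
    "passes_filters",
    "classify_read",
    "classify_alignments",
    "CATEGORIES",
]

CATEGORIES = ("1_intergenic", "2_intragenic", "3_fusion", "4_other")

# SAM CIGAR op codes as emitted by pysam.cigartuples
_BAM_CMATCH, _BAM_CINS, _BAM_CDEL, _BAM_CREF_SKIP = 0, 1, 2, 3
_BAM_CSOFT, _BAM_CHARD, _BAM_CPAD, _BAM_CEQUAL, _BAM_CDIFF = 4, 5, 6, 7, 8
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_OP_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6,
            "=": 7, "X": 8}


@dataclass
class AlignedRead:
    """One alignment reduced to its reference-consuming blocks."""

    read_id: str
    chrom: str
    mapq: int
    blocks: list
    aligned_len: int
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False
    has_hard_clip: bool = False


@dataclass
class ReadClassification:
    read_id: str
    category: str
    te_bp: int
    exon_bp: int
    inter_te_bp: int
    intra_te_bp: int
    te_fraction: float


def blocks_from_cigartuples(chrom: str, pos: int, cigartuples):
    """Reference-consuming blocks from pysam-style (op, length) tuples.

    M/=/X and D advance the reference and stay inside one block (a deletion
    bridges, it never splits); N advances the reference and splits blocks;
    I/S/P consume no reference; H consumes nothing but flags the read.
    Returns (blocks, aligned_len, has_hard_clip) where aligned_len is the
    summed block width.
    """
    blocks = []
    has_hard = False
    ref = pos
    block_start = None
    for op, length in cigartuples:
        if op in (_BAM_CMATCH, _BAM_CEQUAL, _BAM_CDIFF, _BAM_CDEL):
            if block_start is None:
                block_start = ref
            ref += length
        elif op == _BAM_CREF_SKIP:
            if block_start is not None:
                blocks.append(GenomicInterval(chrom, block_start, ref))
                block_start = None
            ref += length
        elif op in (_BAM_CINS, _BAM_CSOFT, _BAM_CPAD):
            pass
        elif op == _BAM_CHARD:
            has_hard = True
        else:
            raise ValueError(f"invalid CIGAR op code {op}")
    if block_start is not None:
        blocks.append(GenomicInterval(chrom, block_start, ref))
    aligned_len = sum(len(b) for b in blocks)
    return blocks, aligned_len, has_hard


def blocks_from_cigar(pos: int, cigar: str, chrom: str = "chr"):
    """String-CIGAR convenience wrapper; returns (blocks, aligned_len)."""
    if pos < 0:
        raise ValueError("pos must be >= 0")
    consumed = "".join(f"{n}{c}" for n, c in _CIGAR_RE.findall(cigar))
    if consumed != cigar:
        raise ValueError(f"invalid CIGAR string {cigar!r}")
    tuples = [(_OP_CODE[c], int(n)) for n, c in _CIGAR_RE.findall(cigar)]
    blocks, aligned_len, _ = blocks_from_cigartuples(chrom, pos, tuples)
    return blocks, aligned_len


def passes_filters(read: AlignedRead, mapq_min: int = 30) -> bool:
    """Uniquely-mapped proxy: primary, MAPQ >= threshold, no hard clips.

    Hard-clipped records are dropped because the aligner emits them for
    re-aligned, quality-compromised reads.
    """
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.mapq < mapq_min
        or read.has_hard_clip
    )


def classify_read(read: AlignedRead, masks: MaskSet,
                  te_frac_min: float = 0.8) -> ReadClassification:
    """Assign one TE-overlapping read to its category (see module docs).

    The read must already have passed filters and overlap >= 1 TE base;
    the intragenic rule is strict: te_fraction must exceed ``te_frac_min``.
    """
    te_bp = overlap_bp(read.blocks, masks.te_all)
    if te_bp == 0:
        raise ValueError(
            f"{read.read_id}: classify_read requires a TE-overlapping read"
        )
    exon_bp = overlap_bp(read.blocks, masks.exon)
    inter_bp = overlap_bp(read.blocks, masks.te_intergenic)
    intra_bp = overlap_bp(read.blocks, masks.te_intragenic)
    frac = intra_bp / read.aligned_len if read.aligned_len else 0.0

    if exon_bp == 0 and inter_bp > 0 and intra_bp == 0:
        category = "1_intergenic"
    elif exon_bp > 0 and inter_bp > 0:
        category = "3_fusion"
    elif exon_bp > 0 and frac > te_frac_min:
        category = "2_intragenic"
    else:
        category = "4_other"
    return ReadClassification(
        read_id=read.read_id, category=category, te_bp=te_bp,
        exon_bp=exon_bp, inter_te_bp=inter_bp, intra_te_bp=intra_bp,
        te_fraction=frac,
    )


@dataclass
class CategoryReport:
    """Counts and proportions over the uniquely-mapped read total."""

    total_records: int = 0
    pass_filter: int = 0
    non_te: int = 0
    discarded: int = 0
    category_counts: dict = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES})

    @property
    def te_overlapping(self) -> int:
        return sum(self.category_counts.values())

    def proportions(self) -> dict:
        """Per-category share of the uniquely mapped (pass-filter) total."""
        denom = self.pass_filter
        return {c: (n / denom if denom else 0.0)
                for c, n in self.category_counts.items()}

    def to_dict(self) -> dict:
        return {
            "total_records": self.total_records,
            "uniquely_mapped_pass_filter": self.pass_filter,
            "discarded": self.discarded,
            "non_te": self.non_te,
            "te_overlapping": self.te_overlapping,
            "category_counts": dict(self.category_counts),
            "category_proportions_of_uniquely_mapped": self.proportions(),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, path) -> None:
        props = self.proportions()
        with open(path, "w", newline="") as fh:
            fh.write("category\tcount\tproportion_of_uniquely_mapped\n")
            for c in CATEGORIES:
                fh.write(f"{c}\t{self.category_counts[c]}\t{props[c]:.6f}\n")


def _as_aligned_read(rec, chrom: str | None) -> AlignedRead:
    if rec.is_unmapped or rec.cigartuples is None:
        return AlignedRead(rec.query_name, chrom or "*", rec.mapping_quality,
                           [], 0, rec.is_secondary, rec.is_supplementary,
                           True, False)
    blocks, alen, hard = blocks_from_cigartuples(
        chrom, rec.reference_start, rec.cigartuples)
    return AlignedRead(rec.query_name, chrom, rec.mapping_quality, blocks,
                       alen, rec.is_secondary, rec.is_supplementary,
                       False, hard)


def classify_alignments(bam_in, masks: MaskSet, output_dir,
                        mapq_min: int = 30,
                        te_frac_min: float = 0.8) -> CategoryReport:
    """Scan an alignment file, writing one output per category plus the
    merged categories-1..3 file that feeds the external assembler.

    Input SAM gives SAM outputs, BAM gives BAM (a BAM must be indexed).
    Each record is classified independently; duplicate records are counted
    twice, never deduplicated.  Returns the category report (also written
    as report.json / report.tsv under ``output_dir``).
    """
    bam_in = str(bam_in)
    is_bam = bam_in.endswith(".bam")
    if is_bam and not (os.path.exists(bam_in + ".bai")
                       or os.path.exists(bam_in[:-4] + ".bai")):
        raise FileNotFoundError(
            f"{bam_in} has no index; run `samtools index {bam_in}` first")
    os.makedirs(output_dir, exist_ok=True)
    ext, wmode = (".bam", "wb") if is_bam else (".sam", "wh")

    report = CategoryReport()
    with pysam.AlignmentFile(bam_in, "rb" if is_bam else "r") as src:
        outs = {
            c: pysam.AlignmentFile(
                os.path.join(output_dir, f"category_{c}{ext}"),
                wmode, template=src)
            for c in CATEGORIES
        }
        merged = pysam.AlignmentFile(
            os.path.join(output_dir, f"categories_1_2_3{ext}"),
            wmode, template=src)
        try:
            for rec in src.fetch(until_eof=True):
                report.total_records += 1
                chrom = rec.reference_name
                read = _as_aligned_read(rec, chrom)
                if not passes_filters(read, mapq_min):
                    report.discarded += 1
                    continue
                report.pass_filter += 1
                if overlap_bp(read.blocks, masks.te_all) == 0:
                    report.non_te += 1
                    continue
                cls = classify_read(read, masks, te_frac_min)
                report.category_counts[cls.category] += 1
                outs[cls.category].write(rec)
                if cls.category != "4_other":
                    merged.write(rec)
        finally:
            for f in outs.values():
                f.close()
            merged.close()
    report.write_json(os.path.join(output_dir, "report.json"))
    report.write_tsv(os.path.join(output_dir, "report.tsv"))
    return report
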