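"""Whole-genome binary masks and interval overlap counting.

The read classifier needs O(1) per-base "is this position TE / exon?"
lookups over whole chromosomes.  Positions covered by at least one
annotation interval are set to 1, everything else is 0; per-chromosome
vectors are held as numpy bool arrays.  Four mask kinds are built per run:
TE_all, TE_intergenic, TE_intragenic and EXON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .formats_io import GenomicInterval

__all__ = [
    "GenomeMask",
    "MaskSet",
    "build_mask",
    "label_genic_context",
    "overlap_bp",
    "build_mask_set",
]

MASK_LABELS = ("TE_all", "TE_intergenic", "TE_intragenic", "EXON")


@dataclass
class GenomeMask:
    """Per-chromosome bit vectors; query outside bounds is an error."""

    sizes: dict
    label: str = "mask"
    bits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, n in self.sizes.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom} has length {n}")
            if chrom not in self.bits:
                self.bits[chrom] = np.zeros(int(n), dtype=bool)

    def popcount(self) -> int:
        return int(sum(int(v.sum()) for v in self.bits.values()))

    def _check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.bits:
            raise KeyError(f"chromosome {chrom} absent from {self.label} mask")
        if start < 0 or end > len(self.bits[chrom]) or start > end:
            raise IndexError(
                f"query {chrom}:{start}-{end} outside chromosome bounds "
                f"(length {len(self.bits[chrom])})"
            )

    def set_interval(self, iv: GenomicInterval) -> None:
        self._check(iv.chrom, iv.start, iv.end)
        self.bits[iv.chrom][iv.start:iv.end] = True

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of set bits in [start, end)."""
        self._check(chrom, start, end)
        return int(self.bits[chrom][start:end].sum())


def build_mask(intervals, sizes: dict, label: str = "mask") -> GenomeMask:
    """OR all intervals into a fresh mask (idempotent under duplication)."""
    mask = GenomeMask(sizes=dict(sizes), label=label)
    for iv in intervals:
        mask.set_interval(iv)
    return mask


def overlap_bp(blocks, mask: GenomeMask) -> int:
    """Total number of block bases whose mask bit is set.

    ``blocks`` are the reference-consuming intervals of one read: sorted,
    disjoint, one chromosome.
    """
    return sum(mask.count(b.chrom, b.start, b.end) for b in blocks)


def label_genic_context(repeats, gene_spans) -> list:
    """Label each repeat intragenic iff it overlaps any gene span by >=1 bp.

    Gene spans are full transcript spans of nonTE genes (so intronic
    repeats come out intragenic); overlap is half-open, so touching
    intervals do not overlap.  Input order is preserved.
    """
    trees: dict = {}
    for span in gene_spans:
        trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end)
    out = []
    for rep in repeats:
        tree = trees.get(rep.interval.chrom)
        hit = bool(tree and tree.overlap(rep.interval.start, rep.interval.end))
        out.append(rep.with_context("intragenic" if hit else "intergenic"))
    return out


@dataclass
class MaskSet:
    """The four masks the classifier consumes, built once per run."""

    te_all: GenomeMask
    te_intergenic: GenomeMask
    te_intragenic: GenomeMask
    exon: GenomeMask


def build_mask_set(repeats, gene_transcripts, sizes: dict) -> MaskSet:
    """Build TE/exon masks from context-labeled repeats and gene models.

    ``repeats`` must already be te_only-filtered; their genic context is
    (re)derived here from the gene transcript spans, so
    TE_all == TE_intergenic OR TE_intragenic by construction.
    """
    spans = [tx.interval for tx in gene_transcripts]
    labeled = label_genic_context(repeats, spans)
    te_iv = [r.interval for r in labeled]
    inter_iv = [r.interval for r in labeled if r.genic_context == "intergenic"]
    intra_iv = [r.interval for r in labeled if r.genic_context == "intragenic"]
    exon_iv = [ex for tx in gene_transcripts for ex in tx.exons]
    return MaskSet(
        te_all=build_mask(te_iv, sizes, "TE_all"),
        te_intergenic=build_mask(inter_iv, sizes, "TE_intergenic"),
        te_intragenic=build_mask(intra_iv, sizes, "TE_intragenic"),
        exon=build_mask(exon_iv, sizes, "EXON"),
    )
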