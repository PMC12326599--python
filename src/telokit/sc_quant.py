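"""Per-cell quantification of genes, isoforms and repeat elements.

The TE annotation is first reconciled against the reference gene
annotation conservatively: any TE-derived transcript sharing >= 1 exonic
bp with a nonTE gene exon is dropped, so reads over shared regions always
count toward the gene.  Surviving TE transcripts and the gene annotation
form one feature index; a barcoded read is assigned within the transcript
layer (gene-priority, unique gene required, best-overlap isoform) and,
independently, to every repeat element it touches.  Counting is per
distinct (cell barcode, feature, UMI) triple, so PCR duplicates collapse
to molecules.  Output is a 10x-style MatrixMarket directory.
"""

from __future__ import annotations

import gzip
import io
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree

from .read_classifier import blocks_from_cigartuples, passes_filters, AlignedRead

__all__ = [
    "BarcodedRead",
    "FeatureIndex",
    "CountMatrix",
    "QuantStats",
    "reconcile_annotations",
    "assign_read",
    "quantify_cells",
    "write_matrix",
    "read_matrix",
]


@dataclass
class BarcodedRead:
    read: AlignedRead
    cell_barcode: str | None
    umi: str | None


@dataclass
class CountMatrix:
    """Sparse barcodes x features UMI counts plus feature metadata."""

    X: sp.csr_matrix
    barcodes: list
    features: pd.DataFrame  # columns: id, name, kind, is_te

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.barcodes), len(self.features)):
            raise ValueError(
                f"matrix shape {self.X.shape} != "
                f"({len(self.barcodes)}, {len(self.features)})")
        if self.features["id"].duplicated().any():
            dup = self.features.loc[self.features["id"].duplicated(), "id"]
            raise ValueError(f"duplicate feature ids: {sorted(set(dup))}")

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.barcodes == other.barcodes
            and self.features.reset_index(drop=True).equals(
                other.features.reset_index(drop=True))
            and (self.X != other.X).nnz == 0
        )


@dataclass
class QuantStats:
    total_records: int = 0
    filtered: int = 0       # failed alignment filters
    missing_tags: int = 0   # no CB or no UB
    off_whitelist: int = 0
    ambiguous: int = 0      # multi-gene in the transcript layer
    unassigned: int = 0     # no feature overlap in either layer
    assigned: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class FeatureIndex:
    """Interval index over gene exons, TE-transcript exons and repeats.

    Transcript-layer entries carry (gene_id, transcript_id, is_te); the
    repeat layer carries element ids.  Queries return exactly what a
    linear scan would.
    """

    def __init__(self, transcripts, repeats) -> None:
        self.tx_trees: dict = {}
        self.rep_trees: dict = {}
        self.transcripts = list(transcripts)
        self.repeats = list(repeats)
        for tx in self.transcripts:
            is_te = tx.source_kind == "TE_derived"
            for ex in tx.exons:
                self.tx_trees.setdefault(ex.chrom, IntervalTree()).addi(
                    ex.start, ex.end,
                    (tx.gene_id, tx.transcript_id, is_te))
        for rep in self.repeats:
            iv = rep.interval
            self.rep_trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, rep.element_id)

    def transcript_hits(self, blocks) -> dict:
        """(gene_id, transcript_id, is_te) -> overlap bp over all blocks."""
        hits: dict = {}
        for b in blocks:
            tree = self.tx_trees.get(b.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(b.start, b.end):
                bp = min(b.end, hit.end) - max(b.start, hit.begin)
                hits[hit.data] = hits.get(hit.data, 0) + bp
        return hits

    def repeat_hits(self, blocks) -> set:
        out = set()
        for b in blocks:
            tree = self.rep_trees.get(b.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(b.start, b.end):
                out.add(hit.data)
        return out


def reconcile_annotations(te_transcripts, gene_transcripts):
    """Drop TE transcripts with any exonic overlap against nonTE gene exons.

    Strand-agnostic, >= 1 bp, exon level only (a TE transcript inside a
    gene intron survives).  Returns (merged transcript list, survivors)
    where merged = genes + surviving TE transcripts; duplicate
    transcript_ids after the merge are an error.
    """
    exon_trees: dict = {}
    for tx in gene_transcripts:
        for ex in tx.exons:
            exon_trees.setdefault(ex.chrom, IntervalTree()).addi(
                ex.start, ex.end)
    survivors = []
    for tt in te_transcripts:
        tx = tt.transcript if hasattr(tt, "transcript") else tt
        tree = exon_trees.get(tx.chrom)
        overlapped = tree is not None and any(
            tree.overlap(ex.start, ex.end) for ex in tx.exons)
        if not overlapped:
            survivors.append(tx)
    merged = list(gene_transcripts) + survivors
    seen: set = set()
    for tx in merged:
        if tx.transcript_id in seen:
            raise ValueError(
                f"duplicate transcript id after merge: {tx.transcript_id}")
        seen.add(tx.transcript_id)
    return merged, survivors


def assign_read(read: BarcodedRead, index: FeatureIndex):
    """Feature assignment for one read: ``(gene_id, transcript_id,
    repeat_ids, status)``.

    Transcript layer: candidates by exon overlap; if any candidate is a
    nonTE gene, TE candidates are dropped (gene priority).  The surviving
    gene_id must be unique, else the read is ambiguous in that layer.  The
    isoform is the candidate transcript with maximal overlap bp; an exact
    tie yields a gene-level count only.  Repeat layer: every overlapped
    element counts, independent of the transcript layer.
    """
    hits = index.transcript_hits(read.read.blocks)
    repeat_ids = index.repeat_hits(read.read.blocks)
    if not hits:
        status = "unassigned" if not repeat_ids else "repeat_only"
        return None, None, repeat_ids, status
    if any(not is_te for (_, _, is_te) in hits):
        hits = {k: v for k, v in hits.items() if not k[2]}
    genes = {gid for (gid, _, _) in hits}
    if len(genes) > 1:
        return None, None, repeat_ids, "ambiguous"
    gene_id = genes.pop()
    best_bp = max(hits.values())
    best = [tid for (gid, tid, _), bp in hits.items() if bp == best_bp]
    transcript_id = best[0] if len(best) == 1 else None
    return gene_id, transcript_id, repeat_ids, "assigned"


def _get_tag(rec, tag):
    try:
        val = rec.get_tag(tag)
    except KeyError:
        return None
    return val if val else None


def quantify_cells(bam, merged_transcripts, repeats,
                   barcode_whitelist=None, mapq_min: int = 30):
    """Scan a CB/UB-tagged alignment file into UMI count matrices.

    Returns ``(tx_matrix, repeat_matrix, stats)``: the transcript matrix
    holds gene- and isoform-level features (TE features flagged via
    source_kind), the repeat matrix one feature per RepeatMasker element
    with >= 1 molecule.  One count per distinct (CB, feature, UB) triple.
    """
    bam = str(bam)
    is_bam = bam.endswith(".bam")
    if is_bam and not (os.path.exists(bam + ".bai")
                       or os.path.exists(bam[:-4] + ".bai")):
        raise FileNotFoundError(
            f"{bam} has no index; run `samtools index {bam}` first")
    index = FeatureIndex(merged_transcripts, repeats)
    whitelist = set(barcode_whitelist) if barcode_whitelist else None

    stats = QuantStats()
    tx_umis: dict = {}   # (barcode, feature_id) -> set of UMIs
    rep_umis: dict = {}
    barcodes_seen: dict = {}  # barcode -> first-seen order

    with pysam.AlignmentFile(bam, "rb" if is_bam else "r") as src:
        for rec in src.fetch(until_eof=True):
            stats.total_records += 1
            if rec.is_unmapped or rec.cigartuples is None:
                stats.filtered += 1
                continue
            blocks, alen, hard = blocks_from_cigartuples(
                rec.reference_name, rec.reference_start, rec.cigartuples)
            read = AlignedRead(rec.query_name, rec.reference_name,
                               rec.mapping_quality, blocks, alen,
                               rec.is_secondary, rec.is_supplementary,
                               False, hard)
            if not passes_filters(read, mapq_min):
                stats.filtered += 1
                continue
            cb, ub = _get_tag(rec, "CB"), _get_tag(rec, "UB")
            if cb is None or ub is None:
                stats.missing_tags += 1
                continue
            if whitelist is not None and cb not in whitelist:
                stats.off_whitelist += 1
                continue
            gene_id, transcript_id, repeat_ids, status = assign_read(
                BarcodedRead(read, cb, ub), index)
            if status == "ambiguous":
                stats.ambiguous += 1
            elif status == "unassigned":
                stats.unassigned += 1
            else:
                stats.assigned += 1
            if cb not in barcodes_seen:
                barcodes_seen[cb] = len(barcodes_seen)
            if gene_id is not None:
                tx_umis.setdefault((cb, gene_id), set()).add(ub)
            if transcript_id is not None:
                tx_umis.setdefault((cb, "iso:" + transcript_id), set()).add(ub)
            for rid in repeat_ids:
                rep_umis.setdefault((cb, rid), set()).add(ub)

    barcodes = sorted(barcodes_seen)
    tx_matrix = _build_matrix(tx_umis, barcodes,
                              _transcript_features(merged_transcripts))
    rep_features = pd.DataFrame(
        [{"id": rid, "name": rid.split("|")[0], "kind": "repeat_element",
          "is_te": True}
         for rid in sorted({rid for (_, rid) in rep_umis})],
        columns=["id", "name", "kind", "is_te"])
    rep_matrix = _build_matrix(rep_umis, barcodes, rep_features)
    return tx_matrix, rep_matrix, stats


def _transcript_features(transcripts) -> pd.DataFrame:
    rows, seen = [], set()
    for tx in transcripts:
        is_te = tx.source_kind == "TE_derived"
        if tx.gene_id not in seen:
            seen.add(tx.gene_id)
            rows.append({"id": tx.gene_id, "name": tx.gene_id,
                         "kind": "gene", "is_te": is_te})
        rows.append({"id": "iso:" + tx.transcript_id,
                     "name": tx.transcript_id, "kind": "isoform",
                     "is_te": is_te})
    return pd.DataFrame(rows, columns=["id", "name", "kind", "is_te"])


def _build_matrix(umi_sets: dict, barcodes, features: pd.DataFrame):
    bidx = {b: i for i, b in enumerate(barcodes)}
    fidx = {f: j for j, f in enumerate(features["id"])}
    rows, cols, data = [], [], []
    for (cb, fid), umis in umi_sets.items():
        if fid in fidx:
            rows.append(bidx[cb])
            cols.append(fidx[fid])
            data.append(len(umis))
    X = sp.csr_matrix(
        (data, (rows, cols)),
        shape=(len(barcodes), len(features)), dtype=np.int64)
    return CountMatrix(X=X, barcodes=list(barcodes), features=features)


# ---------------------------------------------------------------------------
# 10x-style MatrixMarket directory

def _gz_write(path, payload: bytes) -> None:
    # mtime=0 keeps gzip output byte-identical across runs
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            gz.write(payload)


def write_matrix(matrix: CountMatrix, outdir) -> None:
    """10x-formatted directory: matrix.mtx.gz (features x barcodes),
    features.tsv.gz (id, name, kind, is_te), barcodes.tsv.gz."""
    os.makedirs(outdir, exist_ok=True)
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(matrix.X.T))
    _gz_write(os.path.join(outdir, "matrix.mtx.gz"), buf.getvalue())
    feat_lines = "".join(
        f"{r.id}\t{r.name}\t{r.kind}\t{'TE' if r.is_te else 'nonTE'}\n"
        for r in matrix.features.itertuples(index=False))
    _gz_write(os.path.join(outdir, "features.tsv.gz"), feat_lines.encode())
    _gz_write(os.path.join(outdir, "barcodes.tsv.gz"),
              "".join(b + "\n" for b in matrix.barcodes).encode())


def read_matrix(indir) -> CountMatrix:
    with gzip.open(os.path.join(indir, "matrix.mtx.gz"), "rb") as fh:
        X = sp.csr_matrix(scipy.io.mmread(fh).T)
    with gzip.open(os.path.join(indir, "features.tsv.gz"), "rt") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    features = pd.DataFrame(
        [{"id": r[0], "name": r[1], "kind": r[2], "is_te": r[3] == "TE"}
         for r in rows], columns=["id", "name", "kind", "is_te"])
    with gzip.open(os.path.join(indir, "barcodes.tsv.gz"), "rt") as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if X.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {X.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features")
    X = sp.csr_matrix(X, dtype=np.int64)
    return CountMatrix(X=X, barcodes=barcodes, features=features)


def write_stats(stats: QuantStats, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
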