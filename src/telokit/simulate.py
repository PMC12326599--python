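"""Self-consistent toy fixtures with known truth for every pipeline stage.

Generates, from one seeded RNG: a toy genome FASTA, a RepeatMasker-style
table, a gene GTF with canonical GT..AG introns, long reads engineered to
satisfy exactly one classification category each (plus filter decoys),
and barcoded single-cell reads with planted cell-type markers.  Every
generated read's intended label is re-verified against a naive per-base
oracle built directly from the annotation lists, so a fixture that fails
its own construction raises instead of emitting wrong truth.

The default repeat-class mix follows the genome-wide RepeatMasker
superfamily shares (SINE 39%, LINE 32%, LTR 15%, DNA 10%, Retroposon
rounded up so a toy set contains a few).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .formats_io import (
    GenomicInterval,
    RepeatElement,
    Transcript,
    write_fasta,
    write_gtf,
)
from .sc_quant import CountMatrix

__all__ = [
    "ToyReference",
    "SimRead",
    "simulate_reference",
    "simulate_long_reads",
    "simulate_barcoded_reads",
    "simulate_count_matrix",
    "write_sam",
    "DEFAULT_CLASS_MIX",
]

DEFAULT_CLASS_MIX = {"SINE": 0.39, "LINE": 0.32, "LTR": 0.15,
                     "DNA": 0.10, "Retroposon": 0.04}

#: subfamily catalog: class -> [(subfamily, family), ...]
_CATALOG = {
    "SINE": [("AluY", "Alu"), ("AluSz", "Alu"), ("FLAM-A", "Alu"),
             ("MIRb", "MIR")],
    "LINE": [("L1PA3", "L1"), ("L1HS", "L1"), ("L2a", "L2")],
    "LTR": [("HERVH-int", "ERV1"), ("LTR7", "ERV1"), ("MLT1B", "ERVL-MaLR")],
    "DNA": [("MER20", "hAT-Charlie"), ("Charlie1", "hAT-Charlie")],
    "Retroposon": [("SVA_D", "SVA")],
}

_NONTE_ROWS = [("(AT)n", "Simple_repeat", "Simple_repeat"),
               ("G-rich", "Low_complexity", "Low_complexity"),
               ("tRNA-Lys-TTT", "tRNA", "tRNA")]

# toy gene geometry (bp): exon1, intron1, exon2, intron2, exon3
_E1, _I1, _E2, _I2, _E3 = 300, 400, 520, 400, 300
_EXONIC_TE_LEN = 350   # embedded in exon2, leaving 85 bp flanks
_INTRON_TE_LEN = 200

_BASES = np.array(list("ACGT"))


@dataclass
class ToyReference:
    """Toy genome + annotations with placement truth."""

    genome: dict
    sizes: dict
    genes: list                    # Transcript, one isoform each
    repeats: list                  # TE RepeatElement, genic_context truth set
    seed: int
    exonic_te_of: dict = field(default_factory=dict)   # gene_id -> element
    intronic_te_of: dict = field(default_factory=dict)

    @property
    def intergenic_tes(self) -> list:
        return [r for r in self.repeats if r.genic_context == "intergenic"]

    def write(self, outdir) -> dict:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "ref.fa"),
            "rmsk": os.path.join(outdir, "rmsk.tsv"),
            "gtf": os.path.join(outdir, "genes.gtf"),
            "truth": os.path.join(outdir, "reference_truth.json"),
        }
        write_fasta(self.genome, paths["fasta"])
        self.write_rmsk(paths["rmsk"])
        write_gtf(self.genes, paths["gtf"])
        with open(paths["truth"], "w") as fh:
            json.dump({
                "seed": self.seed,
                "genic_context": {r.element_id: r.genic_context
                                  for r in self.repeats},
            }, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths

    def write_rmsk(self, path, include_non_te: bool = True) -> None:
        rows = [{
            "genoName": r.interval.chrom, "genoStart": r.interval.start,
            "genoEnd": r.interval.end, "strand": r.interval.strand,
            "repName": r.subfamily, "repClass": r.superfamily,
            "repFamily": r.family,
        } for r in self.repeats]
        if include_non_te:
            # a few non-TE repeats near the chromosome starts, to exercise
            # the te_only filter; kept clear of genes and TEs
            for i, (chrom, size) in enumerate(sorted(self.sizes.items())):
                for j, (name, cls, fam) in enumerate(_NONTE_ROWS):
                    start = 30 + 60 * j
                    rows.append({"genoName": chrom, "genoStart": start,
                                 "genoEnd": start + 40, "strand": "+",
                                 "repName": name, "repClass": cls,
                                 "repFamily": fam})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _random_seq(rng, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def simulate_reference(seed: int, n_chroms: int = 2, chrom_len: int = 100_000,
                       n_genes: int = 20, n_te: int = 200,
                       te_class_mix: dict | None = None) -> ToyReference:
    """Build the toy genome/RepeatMasker/gene-annotation triplet.

    Genes are three-exon models with GT..AG introns.  Every gene carries
    one TE embedded in its middle exon and one in its first intron
    (intragenic truth); the remaining ``n_te - 2*n_genes`` elements go
    into intergenic gaps with a 300 bp margin from any gene span.
    """
    mix = dict(te_class_mix or DEFAULT_CLASS_MIX)
    probs = np.array(list(mix.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("te_class_mix must sum to 1")
    classes = list(mix)
    n_intergenic = n_te - 2 * n_genes
    if n_intergenic < n_chroms:
        raise ValueError("n_te too small for the requested gene count")

    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    sizes = {c: chrom_len for c in chroms}
    seq = {c: _random_seq(rng, chrom_len) for c in chroms}

    def draw_class():
        cls = classes[int(rng.choice(len(classes), p=probs))]
        sub, fam = _CATALOG[cls][int(rng.integers(len(_CATALOG[cls])))]
        return sub, fam, cls

    def make_repeat(chrom, start, length, context):
        sub, fam, cls = draw_class()
        strand = "+" if rng.random() < 0.5 else "-"
        return RepeatElement(
            interval=GenomicInterval(chrom, start, start + length, strand),
            subfamily=sub, family=fam, superfamily=cls,
            element_id=f"{sub}|{chrom}|{start}|{start + length}",
            genic_context=context)

    genes, repeats = [], []
    exonic_te_of, intronic_te_of = {}, {}
    gene_no = 0
    gap_lists = {}
    span = _E1 + _I1 + _E2 + _I2 + _E3
    for ci, chrom in enumerate(chroms):
        gpc = n_genes // n_chroms + (1 if ci < n_genes % n_chroms else 0)
        step = (chrom_len - 4000) // max(gpc, 1)
        if step < span + 1200:
            raise ValueError("chromosome too short for the gene count")
        gene_starts = [2000 + k * step for k in range(gpc)]
        prev_end = 0
        gaps = []
        for gs in gene_starts:
            gene_no += 1
            gid = f"GENE{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            e1 = GenomicInterval(chrom, gs, gs + _E1, strand)
            e2s = gs + _E1 + _I1
            e2 = GenomicInterval(chrom, e2s, e2s + _E2, strand)
            e3s = e2s + _E2 + _I2
            e3 = GenomicInterval(chrom, e3s, e3s + _E3, strand)
            tx = Transcript(
                transcript_id=gid + ".1", gene_id=gid,
                interval=GenomicInterval(chrom, gs, e3s + _E3, strand),
                exons=[e1, e2, e3])
            genes.append(tx)
            for intron in tx.introns:
                if strand == "-":
                    seq[chrom][intron.end - 2:intron.end] = list("AC")
                    seq[chrom][intron.start:intron.start + 2] = list("CT")
                else:
                    seq[chrom][intron.start:intron.start + 2] = list("GT")
                    seq[chrom][intron.end - 2:intron.end] = list("AG")
            te_ex = make_repeat(
                chrom, e2.start + (_E2 - _EXONIC_TE_LEN) // 2,
                _EXONIC_TE_LEN, "intragenic")
            te_in = make_repeat(
                chrom, e1.end + (_I1 - _INTRON_TE_LEN) // 2,
                _INTRON_TE_LEN, "intragenic")
            repeats += [te_ex, te_in]
            exonic_te_of[gid] = te_ex
            intronic_te_of[gid] = te_in
            gaps.append((prev_end + 300, gs - 300))
            prev_end = gs + span
        gaps.append((prev_end + 300, chrom_len - 300))
        gap_lists[chrom] = [(lo, hi) for lo, hi in gaps if hi - lo > 700]

    # intergenic TEs: first one per chromosome is forced long (anchors the
    # category-1/3 read constructions), the rest drawn 150-600 bp
    per_chrom = np.full(n_chroms, n_intergenic // n_chroms)
    per_chrom[: n_intergenic % n_chroms] += 1
    for ci, chrom in enumerate(chroms):
        cursors = {g: g[0] for g in gap_lists[chrom]}
        gaps = gap_lists[chrom]
        for k in range(int(per_chrom[ci])):
            length = 400 if k == 0 else int(rng.integers(150, 601))
            placed = False
            order = rng.permutation(len(gaps))
            for gi in order:
                gap = gaps[gi]
                pos = cursors[gap] + int(rng.integers(10, 51))
                if pos + length <= gap[1]:
                    repeats.append(
                        make_repeat(chrom, pos, length, "intergenic"))
                    cursors[gap] = pos + length
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"infeasible placement: no gap fits TE #{k} on {chrom}")

    ref = ToyReference(
        genome={c: "".join(seq[c]) for c in chroms}, sizes=sizes,
        genes=genes, repeats=repeats, seed=seed,
        exonic_te_of=exonic_te_of, intronic_te_of=intronic_te_of)
    _check_contexts(ref)
    return ref


def _check_contexts(ref: ToyReference) -> None:
    """All-pairs oracle for the genic-context truth labels."""
    for rep in ref.repeats:
        hit = any(rep.interval.overlaps(tx.interval) for tx in ref.genes)
        want = "intragenic" if hit else "intergenic"
        if rep.genic_context != want:
            raise AssertionError(
                f"{rep.element_id}: placed as {rep.genic_context} "
                f"but overlap oracle says {want}")


# ---------------------------------------------------------------------------
# long reads

@dataclass
class SimRead:
    name: str
    chrom: str
    pos: int            # 0-based leftmost
    mapq: int
    cigar: str
    seq: str
    truth: str          # 1_intergenic .. 4_other | discarded | non_te
    flag: int = 0
    tags: list = field(default_factory=list)


def _read_seq(rng, genome: str, pos: int, cigar_ops) -> str:
    out = []
    ref = pos
    for op, ln in cigar_ops:
        if op in "M=X":
            out.append(genome[ref:ref + ln])
            ref += ln
        elif op in "DN":
            ref += ln
        elif op in "IS":
            out.append("".join(rng.choice(_BASES, size=ln)))
        # H contributes nothing
    return "".join(out)


def _ops(cigar: str):
    import re
    return [(c, int(n)) for n, c in re.findall(r"(\d+)([MIDNSHP=X])", cigar)]


class _BaseOracle:
    """Per-base annotation membership, built by plain loops (independent
    of the mask implementation)."""

    def __init__(self, ref: ToyReference) -> None:
        self.exon: dict = {c: set() for c in ref.sizes}
        self.inter: dict = {c: set() for c in ref.sizes}
        self.intra: dict = {c: set() for c in ref.sizes}
        for tx in ref.genes:
            for ex in tx.exons:
                self.exon[ex.chrom].update(range(ex.start, ex.end))
        for rep in ref.repeats:
            tgt = (self.inter if rep.genic_context == "intergenic"
                   else self.intra)
            tgt[rep.interval.chrom].update(
                range(rep.interval.start, rep.interval.end))

    def category(self, chrom: str, blocks, te_frac_min: float = 0.8) -> str:
        positions = set()
        for s, e in blocks:
            positions.update(range(s, e))
        aligned = len(positions)
        exon_bp = len(positions & self.exon[chrom])
        inter_bp = len(positions & self.inter[chrom])
        intra_bp = len(positions & self.intra[chrom])
        if inter_bp + intra_bp == 0:
            return "non_te"
        if exon_bp == 0 and inter_bp > 0 and intra_bp == 0:
            return "1_intergenic"
        if exon_bp > 0 and inter_bp > 0:
            return "3_fusion"
        if exon_bp > 0 and intra_bp / aligned > te_frac_min:
            return "2_intragenic"
        return "4_other"


def _blocks_of(pos: int, cigar_ops):
    blocks, ref, start = [], pos, None
    for op, ln in cigar_ops:
        if op in "M=XD":
            if start is None:
                start = ref
            ref += ln
        elif op == "N":
            if start is not None:
                blocks.append((start, ref))
                start = None
            ref += ln
    if start is not None:
        blocks.append((start, ref))
    return blocks


def simulate_long_reads(ref: ToyReference, per_category_counts: dict,
                        seed: int, mapq: int = 60,
                        boundary_decoys: int = 0) -> list:
    """Engineer reads that satisfy exactly one category definition each.

    ``per_category_counts`` maps "1_intergenic" / "2_intragenic" /
    "3_fusion" / "4_other" (and optionally "discarded" / "non_te" decoy
    kinds) to read counts.  ``boundary_decoys`` adds category-4 reads
    whose intragenic TE fraction is exactly 0.80 (the strict-> edge).
    Each read's label is re-derived with the per-base oracle; a
    construction that lands in the wrong category raises.
    """
    rng = np.random.default_rng(seed)
    oracle = _BaseOracle(ref)
    reads: list = []
    counter = [0]

    def emit(chrom, pos, cigar, truth, read_mapq=None, check=True):
        ops = _ops(cigar)
        if check:
            got = oracle.category(chrom, _blocks_of(pos, ops))
            if got != truth:
                raise ValueError(
                    f"requested category {truth} impossible: construction "
                    f"at {chrom}:{pos} {cigar} classifies as {got}")
        counter[0] += 1
        reads.append(SimRead(
            name=f"read{counter[0]:05d}_{truth}", chrom=chrom, pos=pos,
            mapq=read_mapq if read_mapq is not None else mapq, cigar=cigar,
            seq=_read_seq(rng, ref.genome[chrom], pos, ops), truth=truth))

    inter_tes = ref.intergenic_tes
    long_tes = [t for t in inter_tes if len(t.interval) >= 200]
    if not long_tes:
        raise ValueError("reference has no intergenic TE >= 200 bp")
    gene_list = ref.genes

    def pick(seq_):
        return seq_[int(rng.integers(len(seq_)))]

    def make_1():
        te = pick(long_tes)
        width = int(rng.integers(80, min(len(te.interval), 180) + 1))
        off = int(rng.integers(0, len(te.interval) - width + 1))
        pos = te.interval.start + off
        style = rng.random()
        if style < 0.25 and width > 40:
            a = width // 2
            cigar = f"{a}M2I{width - a}M"   # insertion: no extra ref span
        elif style < 0.5 and width > 40:
            a, d = width // 2, 3
            cigar = f"{a}M{d}D{width - a - d}M"  # deletion bridges
        elif style < 0.75:
            cigar = f"5S{width}M"
        else:
            cigar = f"{width}M"
        emit(te.interval.chrom, pos, cigar, "1_intergenic")

    def make_2():
        gene = pick(gene_list)
        te = ref.exonic_te_of[gene.gene_id]
        te_len = len(te.interval)
        frac = rng.uniform(0.85, 0.95)
        aligned = int(te_len / frac)
        flank = aligned - te_len          # <= 61 for the toy geometry
        left = int(rng.integers(0, flank + 1))
        pos = te.interval.start - left
        emit(te.interval.chrom, pos, f"{aligned}M", "2_intragenic")

    def make_3():
        gene = pick(gene_list)
        e1 = gene.exons[0]
        same_chrom = [t for t in long_tes
                      if t.interval.chrom == e1.chrom
                      and not t.interval.overlaps(gene.interval)]
        te = pick(same_chrom)
        a = int(rng.integers(60, 121))
        b = int(rng.integers(60, min(120, len(te.interval)) + 1))
        exon_block = (e1.end - a, e1.end)
        te_block = (te.interval.start, te.interval.start + b)
        first, second = sorted([exon_block, te_block])
        gap = second[0] - first[1]
        cigar = (f"{first[1] - first[0]}M{gap}N"
                 f"{second[1] - second[0]}M")
        emit(e1.chrom, first[0], cigar, "3_fusion")

    def make_4():
        gene = pick(gene_list)
        if rng.random() < 0.5:
            te = ref.intronic_te_of[gene.gene_id]   # intron-only TE read
            width = int(rng.integers(80, len(te.interval) + 1))
            off = int(rng.integers(0, len(te.interval) - width + 1))
            emit(te.interval.chrom, te.interval.start + off,
                 f"{width}M", "4_other")
        else:                                       # sub-threshold fraction
            te = ref.exonic_te_of[gene.gene_id]
            te_ov = int(rng.integers(150, 251))
            flank = int(rng.integers(te_ov // 4 + 5, 86))
            pos = te.interval.start - flank
            emit(te.interval.chrom, pos, f"{te_ov + flank}M", "4_other")

    def make_boundary():
        gene = pick(gene_list)
        te = ref.exonic_te_of[gene.gene_id]
        te_ov, flank = 320, 80                       # fraction exactly 0.80
        pos = te.interval.start - flank
        emit(te.interval.chrom, pos, f"{te_ov + flank}M", "4_other")

    def make_discarded():
        te = pick(long_tes)
        pos = te.interval.start + 10
        if rng.random() < 0.5:
            emit(te.interval.chrom, pos, "100M", "discarded",
                 read_mapq=int(rng.integers(0, 30)), check=False)
        else:
            emit(te.interval.chrom, pos, "10H100M", "discarded", check=False)

    def make_non_te():
        gene = pick(gene_list)
        e1 = gene.exons[0]
        width = 100
        pos = e1.start + int(rng.integers(0, _E1 - width + 1))
        emit(e1.chrom, pos, f"{width}M", "non_te")

    makers = {"1_intergenic": make_1, "2_intragenic": make_2,
              "3_fusion": make_3, "4_other": make_4,
              "discarded": make_discarded, "non_te": make_non_te}
    for key, count in per_category_counts.items():
        if key not in makers:
            raise KeyError(f"unknown read kind {key!r}")
        for _ in range(count):
            makers[key]()
    for _ in range(boundary_decoys):
        make_boundary()
    return reads


def write_sam(reads, sizes: dict, path) -> None:
    """Plain-text, coordinate-sorted SAM with @SQ lines from ``sizes``."""
    recs = sorted(reads, key=lambda r: (r.chrom, r.pos, r.name))
    with open(path, "w", newline="") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom in sizes:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{sizes[chrom]}\n")
        for r in recs:
            fields = [r.name, str(r.flag), r.chrom, str(r.pos + 1),
                      str(r.mapq), r.cigar, "*", "0", "0", r.seq, "*"]
            fields += r.tags
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# barcoded single-cell reads

def _encode(idx: int, width: int) -> str:
    digits = []
    for _ in range(width):
        digits.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(digits))


def te_feature_transcripts(ref: ToyReference, n_features: int = 10) -> list:
    """Single-exon TE transcripts over the longest intergenic TEs, with
    "STRG."-style gene labels carrying the subfamily name."""
    tes = sorted(ref.intergenic_tes, key=lambda t: -len(t.interval))
    tes = sorted(tes[:n_features],
                 key=lambda t: (t.interval.chrom, t.interval.start))
    out = []
    for i, te in enumerate(tes, start=1):
        gid = f"STRG.{i}_{te.subfamily}"
        out.append(Transcript(
            transcript_id=gid + ".1", gene_id=gid, interval=te.interval,
            exons=[te.interval], source_kind="TE_derived",
            attributes={"te_subfamilies": te.subfamily,
                        "te_superfamily": te.superfamily}))
    return out


def simulate_barcoded_reads(ref: ToyReference, n_cells_per_type: dict,
                            planted_markers: dict, seed: int,
                            n_te_features: int = 10, n_gene_features: int = 5,
                            baseline_mean: float = 1.0,
                            dup_range: tuple = (1, 3),
                            tissue_of: dict | None = None):
    """Barcoded reads with Poisson molecule counts and PCR duplicates.

    Features are ``n_te_features`` single-exon TE transcripts (STRG.-style
    ids) plus the first ``n_gene_features`` toy genes.  Molecules per
    (cell, feature) are Poisson(baseline + planted effect); each molecule
    is emitted as dup_range[0]..dup_range[1] reads sharing CB and UB, placed inside
    the feature's (TE-free, unambiguous) exon.  Returns
    (reads, te_transcripts, truth, metadata_records) where truth maps
    (barcode, gene_id) -> molecule count.
    """
    rng = np.random.default_rng(seed)
    te_txs = te_feature_transcripts(ref, n_te_features)
    gene_txs = ref.genes[:n_gene_features]
    features = [(tx.gene_id, tx.exons[0]) for tx in te_txs]
    features += [(tx.gene_id, tx.exons[0]) for tx in gene_txs]
    known = {n for n, _ in features}
    for planted in planted_markers.values():
        for fid in planted:
            if fid not in known:
                raise KeyError(f"planted feature {fid} not in annotation")

    reads, truth, meta = [], {}, {}
    read_no = 0
    cell_no = 0
    for ct in sorted(n_cells_per_type):
        planted = planted_markers.get(ct, {})
        for _ in range(n_cells_per_type[ct]):
            barcode = _encode(cell_no, 12)
            cell_no += 1
            meta[barcode] = {
                "tissue": (tissue_of or {}).get(ct, ct),
                "cell_type": ct, "group": ct}
            for fid, exon in features:
                mean = baseline_mean + planted.get(fid, 0.0)
                k = int(rng.poisson(mean))
                if k:
                    truth[(barcode, fid)] = k
                for mol in range(k):
                    umi = _encode(mol, 10)
                    width = 90
                    off = int(rng.integers(0, len(exon) - width + 1))
                    for _ in range(int(rng.integers(dup_range[0],
                                                    dup_range[1] + 1))):
                        read_no += 1
                        reads.append(SimRead(
                            name=f"screads{read_no:06d}", chrom=exon.chrom,
                            pos=exon.start + off, mapq=60,
                            cigar=f"{width}M",
                            seq=ref.genome[exon.chrom][
                                exon.start + off:exon.start + off + width],
                            truth=fid,
                            tags=[f"CB:Z:{barcode}", f"UB:Z:{umi}"]))
    return reads, te_txs, truth, meta


def simulate_count_matrix(seed: int, n_cells_per_type: dict,
                          planted_markers: dict,
                          n_te_features: int = 10,
                          n_gene_features: int = 10,
                          baseline_mean: float = 1.0):
    """Direct Poisson count matrix for the cohort statistics.

    TE features are named ``STRG.<i>_<subfamily>``, background genes
    ``GENE<i>``.  A feature planted as a marker is expressed at its
    planted mean in its own cell type and at mean 0 everywhere else;
    unplanted features sit at ``baseline_mean`` in every cell.  Returns
    (CountMatrix, cell_type labels ndarray).
    """
    rng = np.random.default_rng(seed)
    subs = ["AluY", "L1PA3", "HERVH-int", "MER20", "SVA_D"]
    te_ids = [f"STRG.{i + 1}_{subs[i % len(subs)]}"
              for i in range(n_te_features)]
    gene_ids = [f"GENE{i + 1:04d}" for i in range(n_gene_features)]
    ids = te_ids + gene_ids
    features = pd.DataFrame({
        "id": ids, "name": ids,
        "kind": ["gene"] * len(ids),
        "is_te": [True] * len(te_ids) + [False] * len(gene_ids)})
    marker_features = {f for planted in planted_markers.values()
                       for f in planted}
    barcodes, labels, rows = [], [], []
    cell_no = 0
    for ct in sorted(n_cells_per_type):
        planted = planted_markers.get(ct, {})
        means = np.array([
            planted.get(f, 0.0) if f in marker_features
            else baseline_mean
            for f in ids])
        for _ in range(n_cells_per_type[ct]):
            barcodes.append(_encode(cell_no, 12))
            cell_no += 1
            labels.append(ct)
            rows.append(rng.poisson(means))
    X = sp.csr_matrix(np.asarray(rows, dtype=np.int64))
    return (CountMatrix(X=X, barcodes=barcodes, features=features),
            np.asarray(labels))
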