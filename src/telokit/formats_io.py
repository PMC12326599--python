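"""Readers/writers for the genomic formats the pipeline touches.

All coordinates are normalized to one internal convention at the file
boundary: 0-based, half-open ``[start, end)``, matching SAM/BAM and the
UCSC table browser.  GTF (1-based inclusive) and RepeatMasker ``.out``
(1-based inclusive) are converted on read and write.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "RepeatElement",
    "Transcript",
    "ChromSizes",
    "TE_CLASSES",
    "FormatError",
    "read_repeatmasker",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "group_by_gene",
]

#: repClass labels treated as transposable elements (after "?"-stripping).
#: RC (rolling-circle / Helitron) is retained here and folded into DNA in
#: superfamily summaries.
TE_CLASSES = frozenset({"LINE", "SINE", "LTR", "DNA", "RC", "Retroposon"})

ChromSizes = dict  # chromosome name -> length (bp)


class FormatError(ValueError):
    """Malformed input file (carries the offending line number when known)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class RepeatElement:
    """One RepeatMasker repeat copy with its three-level taxonomy.

    ``superfamily`` is the repClass label with any trailing "?" stripped;
    ``genic_context`` starts "unset" and is filled in by
    :func:`telokit.genome_mask.label_genic_context`.
    """

    interval: GenomicInterval
    subfamily: str
    family: str
    superfamily: str
    element_id: str
    genic_context: str = "unset"  # intergenic | intragenic | unset

    @property
    def is_te(self) -> bool:
        return self.superfamily in TE_CLASSES

    def with_context(self, context: str) -> "RepeatElement":
        return replace(self, genic_context=context)


@dataclass
class Transcript:
    """A transcript model: ordered non-overlapping exons under one span."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list = field(default_factory=list)
    source_kind: str = "nonTE_gene"  # nonTE_gene | TE_derived
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(
                    f"{self.transcript_id}: exon on {ex.chrom}, "
                    f"transcript on {self.interval.chrom}"
                )
            if ex.start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = ex.end
        if self.exons[0].start != self.interval.start or (
            self.exons[-1].end != self.interval.end
        ):
            raise ValueError(
                f"{self.transcript_id}: span does not match exon extremes"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def mature_length(self) -> int:
        """Sum of exon widths (transcript length after intron removal)."""
        return sum(len(ex) for ex in self.exons)

    @property
    def introns(self) -> list:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.chrom, a.end, b.start, self.strand)
                )
        return out


def group_by_gene(transcripts) -> dict:
    """Group transcripts by gene_id, preserving first-appearance order."""
    genes: dict = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)
    return genes


# ---------------------------------------------------------------------------
# RepeatMasker

_UCSC_REQUIRED = ("genoName", "genoStart", "genoEnd", "strand", "repName",
                  "repClass", "repFamily")


def _strip_query(rep_class: str) -> str:
    return rep_class.rstrip("?")


def _element(chrom, start, end, strand, subfamily, family, superfamily):
    return RepeatElement(
        interval=GenomicInterval(chrom, int(start), int(end), strand),
        subfamily=subfamily,
        family=family,
        superfamily=superfamily,
        element_id=f"{subfamily}|{chrom}|{int(start)}|{int(end)}",
    )


def read_repeatmasker(path, dialect: str = "ucsc_table",
                      te_only: bool = False) -> list:
    """Read a RepeatMasker annotation into :class:`RepeatElement` records.

    dialect "ucsc_table": tab-separated UCSC rmsk dump with a header naming
    at least genoName/genoStart/genoEnd/strand/repName/repClass/repFamily;
    coordinates already 0-based half-open.  dialect "rm_out": native
    RepeatMasker ``.out`` (whitespace columns, 1-based inclusive, strand "C"
    meaning minus); converted on read.

    With ``te_only``, rows whose "?"-stripped repClass is outside
    ``TE_CLASSES`` (tRNA, simple repeats, low complexity, ...) are dropped.
    """
    if dialect == "ucsc_table":
        elements = _read_ucsc_table(path)
    elif dialect == "rm_out":
        elements = _read_rm_out(path)
    else:
        raise ValueError(f"unknown RepeatMasker dialect {dialect!r}")
    if te_only:
        elements = [e for e in elements if e.is_te]
    return elements


def _read_ucsc_table(path) -> list:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: malformed rmsk table ({exc})") from exc
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in _UCSC_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: rmsk table lacks columns {missing}")
    out = []
    for idx, row in enumerate(df.itertuples(index=False)):
        lineno = idx + 2  # 1-based, after header
        try:
            start, end = int(row.genoStart), int(row.genoEnd)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}:{lineno}: non-numeric coordinates"
            ) from exc
        strand = row.strand if row.strand in ("+", "-") else "."
        try:
            out.append(_element(row.genoName, start, end, strand,
                                row.repName, row.repFamily,
                                _strip_query(row.repClass)))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def _read_rm_out(path) -> list:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or not fields[0].lstrip("-").isdigit():
                continue  # two header lines + blank separator
            if len(fields) < 11:
                raise FormatError(f"{path}:{lineno}: truncated .out row")
            try:
                chrom = fields[4]
                start = int(fields[5]) - 1  # 1-based inclusive -> half-open
                end = int(fields[6])
                strand = "-" if fields[8] == "C" else fields[8]
                subfamily = fields[9]
                cls_fam = fields[10]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if "/" in cls_fam:
                superfamily, family = cls_fam.split("/", 1)
            else:
                superfamily, family = cls_fam, cls_fam
            out.append(_element(chrom, start, end, strand, subfamily,
                                family, _strip_query(superfamily)))
    return out


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path, source_kind: str = "nonTE_gene") -> list:
    """Read transcript/exon features from a GTF into :class:`Transcript`.

    GTF 1-based inclusive coordinates become internal 0-based half-open.
    Transcript spans are taken from exon extremes; when an explicit
    ``transcript`` feature is present its span must contain all its exons.
    Input order of first appearance is preserved.
    """
    import pyranges

    with open(path) as fh:
        has_rows = any(line.strip() and not line.startswith("#")
                       for line in fh)
    if not has_rows:
        return []
    df = pyranges.read_gtf(str(path)).df  # pyranges converts to 0-based
    if df.empty:
        return []
    for col in ("gene_id", "transcript_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: GTF lacks {col} attributes")
    exons = df[df.Feature == "exon"]
    if exons.transcript_id.isna().any() or (exons.transcript_id == "").any():
        raise FormatError(f"{path}: exon feature lacking transcript_id")
    spans = {}
    for row in df[df.Feature == "transcript"].itertuples(index=False):
        spans[row.transcript_id] = (int(row.Start), int(row.End))

    order: list = []
    by_tx: dict = {}
    for row in exons.itertuples(index=False):
        tid = row.transcript_id
        if tid not in by_tx:
            by_tx[tid] = {
                "gene_id": row.gene_id,
                "chrom": str(row.Chromosome),
                "strand": str(row.Strand),
                "exons": [],
                "attrs": _extra_attrs(row, df.columns),
            }
            order.append(tid)
        by_tx[tid]["exons"].append((int(row.Start), int(row.End)))

    out = []
    for tid in order:
        rec = by_tx[tid]
        ex_sorted = sorted(rec["exons"])
        ivs = [GenomicInterval(rec["chrom"], s, e, rec["strand"])
               for s, e in ex_sorted]
        span = GenomicInterval(rec["chrom"], ex_sorted[0][0],
                               ex_sorted[-1][1], rec["strand"])
        if tid in spans:
            ds, de = spans[tid]
            if span.start < ds or span.end > de:
                raise FormatError(
                    f"{path}: exon of {tid} outside declared transcript span"
                )
        out.append(Transcript(transcript_id=tid, gene_id=rec["gene_id"],
                              interval=span, exons=ivs,
                              source_kind=source_kind,
                              attributes=rec["attrs"]))
    return out


_RESERVED_GTF_COLS = {
    "Chromosome", "Source", "Feature", "Start", "End", "Score", "Strand",
    "Frame", "gene_id", "transcript_id",
}


def _extra_attrs(row, columns) -> dict:
    attrs = {}
    for col in columns:
        if col in _RESERVED_GTF_COLS:
            continue
        val = getattr(row, col, None)
        if isinstance(val, str) and val:
            attrs[col] = val
    return attrs


def _attr_string(gene_id, transcript_id, extra) -> str:
    parts = [f'gene_id "{gene_id}"', f'transcript_id "{transcript_id}"']
    for key in sorted(extra):
        parts.append(f'{key} "{extra[key]}"')
    return "; ".join(parts) + ";"


def write_gtf(transcripts, path, source: str = "telokit") -> None:
    """Write transcripts as GTF 2.2 (1-based inclusive); byte-deterministic.

    ``read_gtf(write_gtf(x))`` reproduces ``x`` (round trip).
    """
    with open(path, "w", newline="") as fh:
        fh.write("##description: telokit transcript annotation\n")
        for tx in transcripts:
            tx.validate()
            attrs = _attr_string(tx.gene_id, tx.transcript_id, tx.attributes)
            iv = tx.interval
            fh.write("\t".join([
                iv.chrom, source, "transcript", str(iv.start + 1),
                str(iv.end), ".", iv.strand, ".", attrs,
            ]) + "\n")
            for ex in tx.exons:
                fh.write("\t".join([
                    ex.chrom, source, "exon", str(ex.start + 1),
                    str(ex.end), ".", ex.strand, ".", attrs,
                ]) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path):
    """Read a FASTA into ``(name -> uppercase sequence, ChromSizes)``."""
    seqs: dict = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise FormatError(f"{path}: duplicate sequence name {rec.id}")
            seqs[rec.id] = str(rec.seq).upper()
    sizes = {name: len(s) for name, s in seqs.items()}
    return seqs, sizes


def write_fasta(seqs: dict, path, width: int = 60) -> None:
    with open(path, "w", newline="") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
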