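"""Splice-site sequence extraction and information-content matrices.

Spliceosomal introns begin with a GT donor dinucleotide and end with an AG
acceptor.  To check that assembled TE-derived isoforms carry real splice
junctions, every intron contributes a donor window (last 3 exonic + first
6 intronic bases) and an acceptor window (last 6 intronic + first 3 exonic
bases), read 5'->3' on the transcript strand.  Position-wise base counts
are turned into probabilities and then information content
IC(b, i) = p(b, i) * (2 - H_i) bits, where H_i is the Shannon entropy of
the base distribution at position i — the quantity a sequence logo draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpliceSiteSet",
    "MotifMatrix",
    "extract_splice_sites",
    "counts_matrix",
    "probability_matrix",
    "information_matrix",
    "motifs_table",
]

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SpliceSiteSet:
    donors: list
    acceptors: list
    donor_window: tuple  # (exonic bp, intronic bp)
    acceptor_window: tuple  # (intronic bp, exonic bp)


@dataclass
class MotifMatrix:
    """positions x {A,C,G,T} matrix in one layer: counts | probability
    | information (bits)."""

    values: pd.DataFrame
    layer: str

    @property
    def width(self) -> int:
        return len(self.values)


def extract_splice_sites(transcripts, genome: dict,
                         donor_window=(3, 6),
                         acceptor_window=(6, 3)) -> SpliceSiteSet:
    """Collect donor/acceptor flanking sequences from every intron.

    Plus-strand intron [s, e): donor = genome[s-3 : s+6], acceptor =
    genome[e-6 : e+3].  Minus-strand sites mirror and reverse-complement so
    the returned strings always read 5'->3' with the GT/AG on the intronic
    side.  Single-exon transcripts contribute nothing; windows running off
    a chromosome end are skipped with a warning.  Ns are retained.
    """
    d_ex, d_in = donor_window
    a_in, a_ex = acceptor_window
    donors, acceptors = [], []
    for tx in transcripts:
        seq = genome.get(tx.chrom)
        if seq is None:
            raise KeyError(f"chromosome {tx.chrom} missing from genome")
        minus = tx.strand == "-"
        for intron in tx.introns:
            s, e = intron.start, intron.end
            if minus:
                d_lo, d_hi = e - d_in, e + d_ex
                a_lo, a_hi = s - a_ex, s + a_in
            else:
                d_lo, d_hi = s - d_ex, s + d_in
                a_lo, a_hi = e - a_in, e + a_ex
            if d_lo < 0 or d_hi > len(seq) or a_lo < 0 or a_hi > len(seq):
                log.warning("splice window outside %s bounds for %s; skipped",
                            tx.chrom, tx.transcript_id)
                continue
            donor = seq[d_lo:d_hi]
            acceptor = seq[a_lo:a_hi]
            if minus:
                donor = reverse_complement(donor)
                acceptor = reverse_complement(acceptor)
            donors.append(donor)
            acceptors.append(acceptor)
    return SpliceSiteSet(donors=donors, acceptors=acceptors,
                         donor_window=donor_window,
                         acceptor_window=acceptor_window)


def counts_matrix(sequences) -> MotifMatrix:
    """Position-wise base counts over equal-width sequences; N not counted."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences to count")
    width = len(sequences[0])
    for seq in sequences:
        if len(seq) != width:
            raise ValueError(
                f"sequence width {len(seq)} != expected {width}")
    counts = np.zeros((width, 4), dtype=np.int64)
    col = {b: j for j, b in enumerate(BASES)}
    for seq in sequences:
        for i, base in enumerate(seq):
            j = col.get(base)
            if j is not None:
                counts[i, j] += 1
    return MotifMatrix(pd.DataFrame(counts, columns=list(BASES)), "counts")


def probability_matrix(counts: MotifMatrix) -> MotifMatrix:
    if counts.layer != "counts":
        raise ValueError("probability_matrix expects a counts layer")
    c = counts.values.to_numpy(dtype=float)
    totals = c.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, c / totals, 0.0)
    return MotifMatrix(pd.DataFrame(p, columns=list(BASES)), "probability")


def information_matrix(counts: MotifMatrix) -> MotifMatrix:
    """Counts -> per-cell information content in bits.

    At position i with n_i > 0: p = counts / n_i, H_i = -sum p log2 p
    (0*log 0 = 0), IC(b, i) = p(b, i) * (2 - H_i).  All-zero positions stay
    zero.  Invariant under scaling all counts by a positive integer.
    """
    p = probability_matrix(counts).values.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = p * (2.0 - entropy)[:, None]
    return MotifMatrix(pd.DataFrame(ic, columns=list(BASES)), "information")


def motifs_table(sites: SpliceSiteSet) -> pd.DataFrame:
    """Long-format table: site_type, position, base, count, probability,
    information_bits — one row per (site, position, base)."""
    frames = []
    for site_type, seqs in (("donor", sites.donors),
                            ("acceptor", sites.acceptors)):
        if not seqs:
            continue
        cnt = counts_matrix(seqs)
        prob = probability_matrix(cnt)
        info = information_matrix(cnt)
        long = cnt.values.stack().rename("count").reset_index()
        long.columns = ["position", "base", "count"]
        long["probability"] = prob.values.stack().to_numpy()
        long["information_bits"] = info.values.stack().to_numpy()
        long.insert(0, "site_type", site_type)
        frames.append(long)
    if not frames:
        return pd.DataFrame(columns=["site_type", "position", "base",
                                     "count", "probability",
                                     "information_bits"])
    return pd.concat(frames, ignore_index=True)
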