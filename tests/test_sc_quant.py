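"""Annotation reconciliation, read assignment and UMI counting."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from telokit.formats_io import GenomicInterval, RepeatElement, Transcript
from telokit.read_classifier import AlignedRead
from telokit.sc_quant import (
    BarcodedRead,
    CountMatrix,
    FeatureIndex,
    assign_read,
    quantify_cells,
    read_matrix,
    reconcile_annotations,
    write_matrix,
)
from telokit.simulate import simulate_barcoded_reads, write_sam


def tx(exons, tid, gid, kind="nonTE_gene", chrom="chr1"):
    ivs = [GenomicInterval(chrom, s, e) for s, e in exons]
    return Transcript(transcript_id=tid, gene_id=gid,
                      interval=GenomicInterval(chrom, ivs[0].start,
                                               ivs[-1].end),
                      exons=ivs, source_kind=kind)


def te_tx(exons, tid, gid):
    return tx(exons, tid, gid, kind="TE_derived")


def bread(blocks, cb="AAAC", umi="GGTT"):
    ivs = [GenomicInterval("chr1", s, e) for s, e in blocks]
    return BarcodedRead(
        AlignedRead("r", "chr1", 60, ivs, sum(len(b) for b in ivs)),
        cb, umi)


class TestReconcile:
    def test_exon_overlap_removed_intron_retained(self):
        genes = [tx([(100, 200), (400, 500)], "G1.1", "G1")]
        te_hit = te_tx([(150, 250)], "S1.1", "STRG.1")
        te_intronic = te_tx([(250, 350)], "S2.1", "STRG.2")
        merged, survivors = reconcile_annotations(
            [te_hit, te_intronic], genes)
        assert [t.transcript_id for t in survivors] == ["S2.1"]
        assert len(merged) == 2

    def test_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(9)
        genes = [tx([(int(s), int(s) + 50)], f"G{i}.1", f"G{i}")
                 for i, s in enumerate(rng.integers(0, 2000, 20))]
        tes = [te_tx([(int(s), int(s) + 40)], f"S{i}.1", f"STRG.{i}")
               for i, s in enumerate(rng.integers(0, 2000, 30))]
        _, survivors = reconcile_annotations(tes, genes)
        expected = [t.transcript_id for t in tes
                    if not any(t.exons[0].overlaps(g.exons[0])
                               or t.exons[0].overlaps(g.exons[-1])
                               for g in genes)]
        assert [t.transcript_id for t in survivors] == expected

    def test_monotone_in_gene_set(self):
        genes = [tx([(100, 200)], "G1.1", "G1")]
        more = genes + [tx([(250, 350)], "G2.1", "G2")]
        tes = [te_tx([(150, 260)], "S1.1", "STRG.1"),
               te_tx([(300, 380)], "S2.1", "STRG.2"),
               te_tx([(500, 600)], "S3.1", "STRG.3")]
        _, s1 = reconcile_annotations(tes, genes)
        _, s2 = reconcile_annotations(tes, more)
        assert {t.transcript_id for t in s2} <= {t.transcript_id for t in s1}

    def test_duplicate_ids_after_merge_error(self):
        genes = [tx([(0, 100)], "X.1", "X")]
        tes = [te_tx([(500, 600)], "X.1", "STRG.1")]
        with pytest.raises(ValueError, match="duplicate"):
            reconcile_annotations(tes, genes)


class TestAssignRead:
    def make_index(self):
        return FeatureIndex(
            [tx([(0, 100)], "G1.1", "G1"),
             tx([(200, 300)], "G2.1", "G2"),
             te_tx([(50, 150)], "S1.1", "STRG.7"),
             te_tx([(50, 160)], "S1.2", "STRG.7")],
            [RepeatElement(GenomicInterval("chr1", 120, 140), "AluY",
                           "Alu", "SINE", "AluY|chr1|120|140")])

    def test_te_only_read_counts_to_te_gene(self):
        gid, tid, reps, status = assign_read(
            bread([(110, 150)]), self.make_index())
        assert gid == "STRG.7" and status == "assigned"

    def test_gene_priority_over_te(self):
        gid, tid, reps, status = assign_read(
            bread([(60, 90)]), self.make_index())
        assert gid == "G1" and tid == "G1.1" and status == "assigned"

    def test_two_genes_is_ambiguous(self):
        idx = self.make_index()
        gid, tid, reps, status = assign_read(
            bread([(80, 100), (200, 220)]), idx)
        assert gid is None and status == "ambiguous"

    def test_isoform_tie_counts_gene_only(self):
        idx = self.make_index()
        gid, tid, reps, status = assign_read(bread([(60, 150)]), idx)
        # gene priority: G1 wins (overlap 40); single gene, single isoform
        assert gid == "G1" and tid == "G1.1"
        gid, tid, reps, status = assign_read(bread([(100, 150)]), idx)
        # TE-only: S1.1 and S1.2 both overlap 50 bp -> tie, gene only
        assert gid == "STRG.7" and tid is None

    def test_best_overlap_isoform(self):
        idx = self.make_index()
        gid, tid, reps, status = assign_read(bread([(100, 155)]), idx)
        assert gid == "STRG.7" and tid == "S1.2"  # 55 vs 50 bp

    def test_repeat_layer_independent(self):
        idx = self.make_index()
        _, _, reps, _ = assign_read(bread([(130, 135)]), idx)
        assert reps == {"AluY|chr1|120|140"}


def quantify_fixture(toy_ref, tmp_path, dup_range=(1, 3), seed=21,
                     planted=None, whitelist=None):
    reads, te_txs, truth, meta = simulate_barcoded_reads(
        toy_ref, {"A": 4, "B": 4}, planted or {}, seed=seed,
        dup_range=dup_range)
    sam = tmp_path / "bc.sam"
    write_sam(reads, toy_ref.sizes, sam)
    merged, _ = reconcile_annotations(te_txs, toy_ref.genes[:5])
    m, repm, stats = quantify_cells(sam, merged, toy_ref.repeats,
                                    barcode_whitelist=whitelist)
    return m, repm, stats, truth, reads


class TestQuantify:
    def test_umi_dedup_to_molecules(self, toy_ref, tmp_path):
        m, _, _, truth, _ = quantify_fixture(toy_ref, tmp_path,
                                             dup_range=(3, 3))
        fid = {f: j for j, f in enumerate(m.features["id"])}
        bid = {b: i for i, b in enumerate(m.barcodes)}
        for (b, f), k in truth.items():
            assert m.X[bid[b], fid[f]] == k
        gene_cols = [j for j, k in enumerate(m.features["kind"])
                     if k == "gene"]
        assert m.X[:, gene_cols].sum() == sum(truth.values())

    def test_record_duplication_leaves_matrix_unchanged(self, toy_ref,
                                                        tmp_path):
        reads, te_txs, truth, meta = simulate_barcoded_reads(
            toy_ref, {"A": 3}, {}, seed=22)
        merged, _ = reconcile_annotations(te_txs, toy_ref.genes[:5])
        sam1, sam2 = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(reads, toy_ref.sizes, sam1)
        write_sam(reads + reads, toy_ref.sizes, sam2)
        m1, _, _ = quantify_cells(sam1, merged, toy_ref.repeats)
        m2, _, _ = quantify_cells(sam2, merged, toy_ref.repeats)
        assert m1.equals(m2)

    def test_whitelist_drops_other_barcodes(self, toy_ref, tmp_path):
        m_all, _, _, truth, _ = quantify_fixture(toy_ref, tmp_path, seed=23)
        keep = m_all.barcodes[:2]
        m, _, stats, _, _ = quantify_fixture(toy_ref, tmp_path, seed=23,
                                             whitelist=keep)
        assert m.barcodes == keep
        assert stats.off_whitelist > 0

    def test_stats_conservation(self, toy_ref, tmp_path):
        _, _, stats, _, reads = quantify_fixture(toy_ref, tmp_path, seed=24)
        assert stats.total_records == len(reads)
        assert (stats.filtered + stats.missing_tags + stats.off_whitelist
                + stats.ambiguous + stats.unassigned + stats.assigned
                ) == stats.total_records

    def test_te_flag_partitions_feature_ids(self, toy_ref, tmp_path):
        m, _, _, _, _ = quantify_fixture(toy_ref, tmp_path, seed=25)
        te = m.features[m.features.is_te]
        non = m.features[~m.features.is_te]
        assert te.id.str.contains("STRG.", regex=False).all()
        assert not non.id.str.contains("STRG.", regex=False).any()

    def test_reads_without_tags_are_skipped(self, toy_ref, tmp_path):
        reads, te_txs, truth, _ = simulate_barcoded_reads(
            toy_ref, {"A": 2}, {}, seed=26)
        for r in reads[: len(reads) // 2]:
            r.tags = []
        sam = tmp_path / "nt.sam"
        write_sam(reads, toy_ref.sizes, sam)
        merged, _ = reconcile_annotations(te_txs, toy_ref.genes[:5])
        _, _, stats = quantify_cells(sam, merged, toy_ref.repeats)
        assert stats.missing_tags == len(reads) // 2


class TestMatrixIO:
    def make_matrix(self):
        X = sp.csr_matrix(np.array([[0, 2], [1, 0]], dtype=np.int64))
        features = pd.DataFrame({
            "id": ["G1", "STRG.1_AluY"], "name": ["G1", "STRG.1_AluY"],
            "kind": ["gene", "gene"], "is_te": [False, True]})
        return CountMatrix(X=X, barcodes=["AAAA", "CCCC"], features=features)

    def test_round_trip(self, tmp_path):
        m = self.make_matrix()
        write_matrix(m, tmp_path / "mx")
        assert read_matrix(tmp_path / "mx").equals(m)

    def test_empty_matrix_round_trip(self, tmp_path):
        m = CountMatrix(
            X=sp.csr_matrix((0, 0), dtype=np.int64), barcodes=[],
            features=pd.DataFrame(columns=["id", "name", "kind", "is_te"]))
        write_matrix(m, tmp_path / "mx")
        back = read_matrix(tmp_path / "mx")
        assert back.X.shape == (0, 0) and back.barcodes == []

    def test_writes_are_byte_stable(self, tmp_path):
        m = self.make_matrix()
        write_matrix(m, tmp_path / "a")
        write_matrix(m, tmp_path / "b")
        for name in ("matrix.mtx.gz", "features.tsv.gz", "barcodes.tsv.gz"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_random_sparse_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        X = sp.random(30, 40, density=0.1, random_state=np.random.RandomState(11),
                      data_rvs=lambda n: rng.integers(1, 20, n)).tocsr()
        X = sp.csr_matrix(X, dtype=np.int64)
        ids = [f"F{i}" for i in range(40)]
        m = CountMatrix(
            X=X, barcodes=[f"BC{i:03d}" for i in range(30)],
            features=pd.DataFrame({
                "id": ids, "name": ids, "kind": ["gene"] * 40,
                "is_te": [i % 3 == 0 for i in range(40)]}))
        write_matrix(m, tmp_path / "mx")
        assert read_matrix(tmp_path / "mx").equals(m)

    def test_duplicate_feature_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CountMatrix(
                X=sp.csr_matrix((1, 2), dtype=np.int64), barcodes=["A"],
                features=pd.DataFrame({
                    "id": ["F", "F"], "name": ["F", "F"],
                    "kind": ["gene", "gene"], "is_te": [False, False]}))
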