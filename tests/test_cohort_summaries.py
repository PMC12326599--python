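"""Normalization, TE fractions, tissue sets and marker statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as sps

from telokit.cohort_summaries import (
    CellMetadata,
    class_composition_per_group,
    normalize_log1p,
    rank_te_markers,
    te_fraction_per_cell,
    tissue_te_sets,
)
from telokit.sc_quant import CountMatrix
from telokit.simulate import simulate_count_matrix


def matrix_from(arr, te_flags=None, ids=None):
    arr = np.asarray(arr, dtype=np.int64)
    n, p = arr.shape
    ids = ids or [f"F{j}" for j in range(p)]
    return CountMatrix(
        X=sp.csr_matrix(arr), barcodes=[f"BC{i:03d}" for i in range(n)],
        features=pd.DataFrame({
            "id": ids, "name": ids, "kind": ["gene"] * p,
            "is_te": te_flags if te_flags is not None else [False] * p}))


class TestNormalize:
    def test_median_target_scaling(self):
        m = matrix_from([[10, 0], [10, 20]])  # totals 10 and 30, median 20
        norm = normalize_log1p(m)
        X = norm.X.toarray()
        assert X[0, 0] == pytest.approx(np.log1p(20.0))
        assert X[1, 1] == pytest.approx(np.log1p(20 * 2 / 3))

    def test_single_cell_scale_is_identity(self):
        m = matrix_from([[3, 5]])
        X = normalize_log1p(m).X.toarray()
        assert X[0, 0] == pytest.approx(np.log1p(3.0))

    def test_all_zero_matrix_unchanged(self, caplog):
        m = matrix_from([[0, 0], [0, 0]])
        with caplog.at_level("WARNING"):
            norm = normalize_log1p(m)
        assert norm.X.nnz == 0
        assert "zero" in caplog.text

    def test_matches_scanpy_normalize_total(self):
        import warnings
        import anndata

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import scanpy as sc
        rng = np.random.default_rng(17)
        counts = rng.poisson(2.0, size=(30, 15))
        m = matrix_from(counts)
        ours = normalize_log1p(m).X.toarray()
        ad = anndata.AnnData(sp.csr_matrix(counts.astype(np.float32)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.normalize_total(ad)
            sc.pp.log1p(ad)
        assert np.allclose(ours, ad.X.toarray(), atol=1e-5)


class TestTeFraction:
    def test_feature_mode_counts_detected_features(self):
        m = matrix_from([[1, 1, 1, 1, 1, 1, 1, 1, 5, 9]],
                        te_flags=[False] * 8 + [True] * 2)
        frac, _, _ = te_fraction_per_cell(m, mode="features")
        assert frac[0] == pytest.approx(0.2)

    def test_umi_mode_uses_counts(self):
        m = matrix_from([[6, 2], [0, 0]], te_flags=[False, True])
        frac, means, n_empty = te_fraction_per_cell(
            m, mode="umis", tissues=["liver", "liver"])
        assert frac[0] == pytest.approx(0.25)
        assert n_empty == 1
        assert means["liver"] == pytest.approx(0.25)  # empty cell excluded

    def test_no_te_features_gives_zero(self):
        m = matrix_from([[2, 3]], te_flags=[False, False])
        frac, _, _ = te_fraction_per_cell(m)
        assert frac[0] == 0.0

    def test_random_against_loop_oracle_and_bounds(self):
        rng = np.random.default_rng(19)
        counts = rng.poisson(1.0, size=(25, 12))
        te = [j % 4 == 0 for j in range(12)]
        m = matrix_from(counts, te_flags=te)
        frac, _, _ = te_fraction_per_cell(m, mode="features")
        for i in range(25):
            nz = counts[i] > 0
            expect = (nz & np.array(te)).sum() / nz.sum() if nz.any() else 0
            assert frac[i] == pytest.approx(expect)
        assert ((frac >= 0) & (frac <= 1)).all()


class TestTissueSets:
    def make(self):
        # tissue A: cells 0-1, tissue B: cells 2-3
        counts = np.array([
            [80, 60, 0, 5],
            [70, 60, 0, 5],
            [10, 60, 90, 5],
            [10, 60, 90, 5],
        ])
        m = matrix_from(counts, te_flags=[True, True, True, False],
                        ids=["t1", "t2", "t3", "g1"])
        return m, ["A", "A", "B", "B"]

    def test_threshold_and_exclusive_sets(self):
        m, tissues = self.make()
        sets, inter = tissue_te_sets(m, tissues, threshold=100.0)
        assert sets["A"] == {"t1", "t2"}
        assert sets["B"] == {"t2", "t3"}
        assert inter[("A",)] == 1 and inter[("B",)] == 1
        assert inter[("A", "B")] == 1

    def test_threshold_zero_includes_every_expressed_te(self):
        m, tissues = self.make()
        sets, _ = tissue_te_sets(m, tissues, threshold=0.0)
        assert sets["A"] == {"t1", "t2", "t3"}

    def test_intersections_partition_union(self):
        rng = np.random.default_rng(23)
        counts = rng.integers(0, 60, size=(30, 20))
        m = matrix_from(counts, te_flags=[True] * 20)
        tissues = rng.choice(["A", "B", "C"], 30)
        sets, inter = tissue_te_sets(m, tissues, threshold=150.0)
        union = frozenset().union(*sets.values())
        assert sum(inter.values()) == len(union)
        # brute-force power-set oracle
        for r in range(1, 4):
            for combo in itertools.combinations(sets, r):
                inside = frozenset.intersection(*(sets[t] for t in combo))
                outside = frozenset().union(
                    *(sets[t] for t in sets if t not in combo),
                    frozenset())
                expect = len(inside - outside)
                assert inter.get(combo, 0) == expect


class TestClassComposition:
    def test_proportions(self):
        df = class_composition_per_group(
            {"g": {"a", "b", "c", "d", "e"}},
            {"a": "LINE", "b": "LINE", "c": "LINE", "d": "LINE",
             "e": "SINE"})
        row = df.iloc[0]
        assert row["prop_LINE"] == pytest.approx(0.8)
        assert row["count_SINE"] == 1

    def test_empty_group_flagged(self):
        df = class_composition_per_group({"g": set()}, {})
        assert not df.iloc[0]["defined"]
        assert df.iloc[0]["n_features"] == 0

    def test_unmapped_feature_errors(self):
        with pytest.raises(KeyError, match="without superfamily"):
            class_composition_per_group({"g": {"x"}}, {})


class TestMarkers:
    def test_planted_marker_detected(self):
        m, labels = simulate_count_matrix(
            31, {"A": 30, "B": 120}, {"A": {"STRG.1_AluY": 20.0}})
        norm = normalize_log1p(m)
        results, te_subset, sig = rank_te_markers(norm, labels)
        hit = te_subset[(te_subset.cell_type == "A")
                        & (te_subset.feature == "STRG.1_AluY")]
        assert len(hit) == 1
        assert hit.iloc[0].p_adj < 0.05 and hit.iloc[0].log2fc > 0

    def test_no_strg_features_gives_empty_subset(self):
        m, labels = simulate_count_matrix(
            32, {"A": 10, "B": 10}, {}, n_te_features=0)
        _, te_subset, sig = rank_te_markers(normalize_log1p(m), labels)
        assert te_subset.empty and sig == {}

    def test_bh_monotone_and_single_feature_identity(self):
        m, labels = simulate_count_matrix(33, {"A": 15, "B": 15}, {})
        results, _, _ = rank_te_markers(normalize_log1p(m), labels)
        for ct, grp in results.groupby("cell_type"):
            grp = grp.sort_values("p")
            assert (grp.p_adj >= grp.p - 1e-12).all()
            assert grp.p_adj.is_monotonic_increasing
        single, labels1 = simulate_count_matrix(
            34, {"A": 12, "B": 12}, {}, n_te_features=1, n_gene_features=0)
        res, _, _ = rank_te_markers(normalize_log1p(single), labels1)
        assert np.allclose(res.p, res.p_adj)

    def test_z_matches_scipy_mannwhitney(self):
        rng = np.random.default_rng(35)
        x = rng.poisson(3.0, size=(40, 1)).astype(float)
        m = matrix_from(x.astype(np.int64))
        labels = np.array(["A"] * 15 + ["B"] * 25)
        res, _, _ = rank_te_markers(
            CountMatrix(X=sp.csr_matrix(x), barcodes=m.barcodes,
                        features=m.features),
            labels)
        a = x[labels == "A", 0]
        b = x[labels == "B", 0]
        expect = sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic",
                                  use_continuity=False).pvalue
        got = res[res.cell_type == "A"].iloc[0].p
        assert got == pytest.approx(expect, rel=1e-9)

    def test_permutation_calibration_loose_bound(self):
        flags = 0
        n_feat, n_types, reps = 15, 2, 30
        for seed in range(reps):
            m, labels = simulate_count_matrix(
                1000 + seed, {"A": 25, "B": 25}, {},
                n_te_features=n_feat, n_gene_features=0)
            _, te_subset, _ = rank_te_markers(normalize_log1p(m), labels)
            flags += len(te_subset)
        bound = 0.05 * n_feat * n_types * 1.5
        assert flags / reps <= bound


class TestMetadata:
    def test_duplicate_barcodes_rejected(self):
        df = pd.DataFrame({"tissue": ["a", "b"], "cell_type": ["x", "y"],
                           "group": ["g", "g"]}, index=["BC1", "BC1"])
        with pytest.raises(ValueError, match="duplicate"):
            CellMetadata(df)

    def test_labels_follow_barcode_order(self):
        meta = CellMetadata.from_records({
            "BC1": {"tissue": "liver", "cell_type": "hep", "group": "x"},
            "BC2": {"tissue": "lung", "cell_type": "at2", "group": "x"}})
        got = meta.labels_for(["BC2", "BC1"], "tissue")
        assert list(got) == ["lung", "liver"]
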