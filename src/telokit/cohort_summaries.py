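"""Downstream statistics on per-cell TE count matrices.

Covers the cohort-level questions asked of the quantified matrices:
how much of each cell's transcriptome is TE-derived, which TE transcripts
are robustly expressed per tissue (and how tissues share them), the
superfamily composition of those sets, and which TE transcripts mark
specific cell types (one-vs-rest Wilcoxon rank-sum with Benjamini-
Hochberg correction; TE features are recognized by a "STRG." gene label).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .sc_quant import CountMatrix
from .te_annotator import SUPERFAMILIES

__all__ = [
    "CellMetadata",
    "normalize_log1p",
    "te_fraction_per_cell",
    "tissue_te_sets",
    "class_composition_per_group",
    "rank_te_markers",
]

log = logging.getLogger(__name__)


@dataclass
class CellMetadata:
    """barcode -> tissue / cell_type / group labels."""

    table: pd.DataFrame  # index: barcode; columns: tissue, cell_type, group

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate barcodes in cell metadata")

    @classmethod
    def from_records(cls, records: dict) -> "CellMetadata":
        df = pd.DataFrame.from_dict(records, orient="index")
        for col in ("tissue", "cell_type", "group"):
            if col not in df.columns:
                df[col] = ""
        return cls(df[["tissue", "cell_type", "group"]])

    def labels_for(self, barcodes, column: str) -> np.ndarray:
        return self.table.reindex(barcodes)[column].to_numpy()


def normalize_log1p(matrix: CountMatrix, target_sum: float | None = None):
    """Depth normalization then log1p, as standard scRNA-seq preprocessing.

    Each cell's counts are scaled so its total equals ``target_sum``
    (default: the median of per-cell totals, the normalize-total default),
    then transformed with natural log(1 + x).  Zero-total cells are left
    at zero with a warning.
    """
    X = sp.csr_matrix(matrix.X, dtype=np.float64, copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    nonzero = totals > 0
    if not nonzero.any():
        log.warning("normalize_log1p: all cells have zero total counts")
        return CountMatrix(X=X, barcodes=list(matrix.barcodes),
                           features=matrix.features.copy())
    if target_sum is None:
        target_sum = float(np.median(totals[nonzero]))
    if (~nonzero).any():
        log.warning("normalize_log1p: %d zero-total cells left at zero",
                    int((~nonzero).sum()))
    scale = np.ones_like(totals)
    scale[nonzero] = target_sum / totals[nonzero]
    X = sp.csr_matrix(sp.diags(scale) @ X)
    X.data = np.log1p(X.data)
    return CountMatrix(X=X, barcodes=list(matrix.barcodes),
                       features=matrix.features.copy())


def te_fraction_per_cell(matrix: CountMatrix, mode: str = "features",
                         tissues=None):
    """Per-cell TE share of the transcriptome, optionally averaged by tissue.

    mode "features": (# nonzero TE features) / (# nonzero features);
    mode "umis": TE count share of the cell's total counts.  Cells with
    nothing detected are excluded from tissue means and reported.
    Returns (per-cell ndarray, tissue-mean dict or None, n_empty_cells).
    """
    if mode not in ("features", "umis"):
        raise ValueError(f"unknown mode {mode!r}")
    is_te = matrix.features["is_te"].to_numpy(dtype=bool)
    X = sp.csr_matrix(matrix.X)
    if mode == "features":
        nz = X.copy()
        nz.data = (nz.data != 0).astype(np.float64)
        total = np.asarray(nz.sum(axis=1)).ravel()
        te = np.asarray(nz[:, is_te].sum(axis=1)).ravel()
    else:
        total = np.asarray(X.sum(axis=1)).ravel()
        te = np.asarray(X[:, is_te].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, te / total, 0.0)
    n_empty = int((total == 0).sum())
    tissue_means = None
    if tissues is not None:
        tissues = np.asarray(tissues)
        keep = total > 0
        tissue_means = {
            t: float(frac[(tissues == t) & keep].mean())
            if ((tissues == t) & keep).any() else float("nan")
            for t in pd.unique(tissues)
        }
    return frac, tissue_means, n_empty


def tissue_te_sets(normalized: CountMatrix, tissues, threshold: float = 100.0):
    """Per-tissue sets of TE features with summed normalized expression
    >= threshold, plus exact UpSet-style intersection sizes.

    Returns (sets: tissue -> frozenset of feature ids, intersections:
    tuple-of-tissues -> count).  Intersection regions partition the union
    of qualifying features: each feature is counted once, under exactly
    the combination of tissues whose set contains it.
    """
    tissues = np.asarray(tissues)
    is_te = normalized.features["is_te"].to_numpy(dtype=bool)
    ids = normalized.features["id"].to_numpy()
    X = sp.csr_matrix(normalized.X)
    sets: dict = {}
    for t in pd.unique(tissues):
        cells = tissues == t
        sums = np.asarray(X[cells][:, is_te].sum(axis=0)).ravel()
        sets[t] = frozenset(ids[is_te][sums >= threshold])
    names = list(sets)
    intersections: dict = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = frozenset.intersection(*(sets[t] for t in combo))
            outside = frozenset().union(
                *(sets[t] for t in names if t not in combo)) if (
                    len(combo) < len(names)) else frozenset()
            n = len(inside - outside)
            if n:
                intersections[combo] = n
    return sets, intersections


def class_composition_per_group(group_sets: dict, superfamily_of: dict):
    """Superfamily counts/proportions of each group's TE feature set.

    ``superfamily_of`` must cover every feature in every set; unmapped
    features are an error naming the offenders.  Empty groups report zero
    counts with proportions flagged undefined (all-zero row).
    """
    rows = []
    for group, features in group_sets.items():
        missing = [f for f in features if f not in superfamily_of]
        if missing:
            raise KeyError(
                f"group {group}: features without superfamily: "
                f"{sorted(missing)[:5]}")
        counts = {cls: 0 for cls in SUPERFAMILIES}
        for f in features:
            counts[superfamily_of[f]] += 1
        total = sum(counts.values())
        row = {"group": group, "n_features": total, "defined": total > 0}
        for cls in SUPERFAMILIES:
            row[f"count_{cls}"] = counts[cls]
            row[f"prop_{cls}"] = counts[cls] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _ranksum_one_vs_rest(X: np.ndarray, in_group: np.ndarray):
    """Vectorized tie-corrected rank-sum z and two-sided p per feature.

    z = (R1 - mu) / sigma with mu = n1(n+1)/2 and
    sigma^2 = n1 n2 / 12 * ((n + 1) - sum(t^3 - t) / (n(n-1))).
    """
    n = X.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = sps.rankdata(X, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = np.sqrt(sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma > 0, (r1 - mu) / sigma, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    return z, np.clip(p, 0.0, 1.0)


def rank_te_markers(normalized: CountMatrix, cell_types,
                    alpha: float = 0.05, te_label: str = "STRG."):
    """One-vs-rest rank-sum markers per cell type, BH-corrected.

    For each cell type with at least one cell in both groups, every
    feature is tested with the tie-corrected normal approximation of the
    Wilcoxon rank-sum statistic; p-values are Benjamini-Hochberg adjusted
    across features within the cell type.  Log2 fold change compares
    group means of expm1(normalized) values.  Returns (all results,
    TE-only subset, per-cell-type significant-TE counts): TE rows are
    those whose feature id contains ``te_label`` with adjusted p < alpha
    and positive fold change is NOT required (matching an unfiltered
    rank-genes-groups table).
    """
    cell_types = np.asarray(cell_types)
    X = np.asarray(normalized.X.todense(), dtype=np.float64)
    ids = normalized.features["id"].to_numpy()
    frames = []
    for ct in pd.unique(cell_types):
        in_group = cell_types == ct
        if in_group.sum() < 1 or (~in_group).sum() < 1:
            log.warning("cell type %s has an empty contrast; skipped", ct)
            continue
        z, p = _ranksum_one_vs_rest(X, in_group)
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        m1 = np.expm1(X[in_group]).mean(axis=0)
        m2 = np.expm1(X[~in_group]).mean(axis=0)
        lfc = np.log2((m1 + 1e-9) / (m2 + 1e-9))
        frames.append(pd.DataFrame({
            "cell_type": ct, "feature": ids, "z": z, "p": p,
            "p_adj": p_adj, "log2fc": lfc,
            "is_te_derived": [te_label in f for f in ids],
        }))
    results = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["cell_type", "feature", "z", "p",
                                          "p_adj", "log2fc",
                                          "is_te_derived"]))
    te_subset = results[results.is_te_derived
                        & (results.p_adj < alpha)].reset_index(drop=True)
    sig_counts = (te_subset.groupby("cell_type").size().to_dict()
                  if len(te_subset) else {})
    return results, te_subset, sig_counts
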