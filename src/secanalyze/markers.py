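"""Cluster-restricted differential expression for scRNA-seq counts.

The criterion is deliberately simple and threshold-based: a gene is a
marker of a cluster when it is at least 1.28-fold overexpressed there
(ratio of mean normalized expression vs all other cells), detected in more
than 25% of the cluster's cells, and its two-sided Wilcoxon rank-sum
p-value is below 0.01. No multiple-testing correction is applied by
default — the thresholds are raw p-values by design (a Benjamini-Hochberg
option is available). The same machinery, with groups defined by condition
within one cluster, yields control-vs-knockout DEG lists.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite

__all__ = [
    "MarkerCriterion",
    "MarkerResult",
    "CountMatrix",
    "ConditionDEGResult",
    "normalize_counts",
    "cluster_markers",
    "condition_deg",
    "markers_table",
]


@dataclass(frozen=True)
class MarkerCriterion:
    """Thresholds of the marker rule: fold, expressing fraction, p-value."""

    min_fold: float = 1.28
    min_pct: float = 0.25
    max_p: float = 0.01

    def __post_init__(self) -> None:
        if not self.min_fold > 1:
            raise ValueError("min_fold must be > 1")
        if not 0 < self.min_pct < 1:
            raise ValueError("min_pct must be in (0, 1)")
        if not 0 < self.max_p < 1:
            raise ValueError("max_p must be in (0, 1)")


@dataclass(frozen=True)
class MarkerResult:
    """Per-gene outcome of the marker test.

    ``fold_change`` is target/rest on de-logged mean normalized expression;
    ``pct_target``/``pct_rest`` are expressing-cell fractions (raw count >
    0); ``direction`` is 'up' when fold >= 1, else 'down'; ``passes``
    applies the criterion (up: fold >= min_fold; down: fold <= 1/min_fold).
    """

    gene_id: str
    fold_change: float
    pct_target: float
    pct_rest: float
    p_value: float
    direction: str
    passes: bool


class CountMatrix:
    """Genes x cells raw counts with per-cell cluster/condition labels."""

    def __init__(
        self,
        counts,
        gene_ids: Sequence[str],
        cell_ids: Sequence[str],
        clusters: Sequence[str],
        conditions: Sequence[str] | None = None,
    ):
        self.counts = sparse.csr_matrix(counts)
        if self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.gene_ids = list(gene_ids)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match matrix rows")
        n_cells = self.counts.shape[1]
        if len(cell_ids) != n_cells or len(clusters) != n_cells:
            raise ValueError("cell labels do not match matrix columns")
        if conditions is not None and len(conditions) != n_cells:
            raise ValueError("condition labels do not match matrix columns")
        self.cells = pd.DataFrame(
            {
                "cluster": list(clusters),
                "condition": list(conditions) if conditions is not None else "",
            },
            index=pd.Index(list(cell_ids), name="cell_id"),
        )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def load(cls, mtx_path, genes_path, cells_path) -> "CountMatrix":
        """Load MatrixMarket counts plus genes/cells TSV sidecars."""
        counts = sparse.csr_matrix(mmread(os.fspath(mtx_path)))
        genes = pd.read_csv(genes_path, sep="\t")
        cells = pd.read_csv(cells_path, sep="\t")
        conditions = cells["condition"] if "condition" in cells else None
        return cls(
            counts,
            genes["gene_id"].tolist(),
            cells["cell_id"].tolist(),
            cells["cluster"].tolist(),
            None if conditions is None else conditions.tolist(),
        )

    def save(self, mtx_path, genes_path, cells_path) -> None:
        mmwrite(os.fspath(mtx_path), sparse.coo_matrix(self.counts))
        pd.DataFrame({"gene_id": self.gene_ids, "gene_name": self.gene_ids}).to_csv(
            genes_path, sep="\t", index=False
        )
        self.cells.reset_index().to_csv(cells_path, sep="\t", index=False)


def normalize_counts(matrix: CountMatrix, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalization to ``target_sum`` per cell, then log1p.

    Returns a dense genes x cells float array. All-zero cells get size
    factor 1 (their normalized vector stays zero) with a warning. The
    normalized vector of a cell is invariant to scaling its counts.
    """
    X = np.asarray(matrix.counts.todense(), dtype=float)
    lib = X.sum(axis=0)
    zero = lib == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} all-zero cell(s): size factor set to 1",
            stacklevel=2,
        )
    scale = np.where(zero, 1.0, target_sum / np.where(zero, 1.0, lib))
    return np.log1p(X * scale)


def _ranksum_p(xt: np.ndarray, xr: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Wilcoxon rank-sum (asymptotic, tie-corrected)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                xt, xr, alternative="two-sided", method="asymptotic", axis=1
            )
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)


def _test_groups(
    matrix: CountMatrix,
    norm: np.ndarray,
    idx_t: np.ndarray,
    idx_r: np.ndarray,
    criterion: MarkerCriterion,
    pct_rule: str,
) -> list[MarkerResult]:
    raw = matrix.counts
    mean_t = norm[:, idx_t].mean(axis=1)
    mean_r = norm[:, idx_r].mean(axis=1)
    # de-log the group means and add pseudocount 1 on both sides: the
    # standard marker fold-change convention, finite for all-zero genes
    fold = (np.expm1(mean_t) + 1.0) / (np.expm1(mean_r) + 1.0)
    pct_t = np.asarray((raw[:, idx_t] > 0).mean(axis=1)).ravel()
    pct_r = np.asarray((raw[:, idx_r] > 0).mean(axis=1)).ravel()
    p = _ranksum_p(norm[:, idx_t], norm[:, idx_r])
    up = fold >= 1.0
    fold_ok = np.where(up, fold >= criterion.min_fold, fold <= 1.0 / criterion.min_fold)
    if pct_rule == "target":
        pct_ok = pct_t > criterion.min_pct
    else:  # either group, keeping the test symmetric under label swap
        pct_ok = np.maximum(pct_t, pct_r) > criterion.min_pct
    passes = fold_ok & pct_ok & (p < criterion.max_p)
    return [
        MarkerResult(
            gene_id=matrix.gene_ids[i],
            fold_change=float(fold[i]),
            pct_target=float(pct_t[i]),
            pct_rest=float(pct_r[i]),
            p_value=float(p[i]),
            direction="up" if up[i] else "down",
            passes=bool(passes[i]),
        )
        for i in range(matrix.n_genes)
    ]


def cluster_markers(
    matrix: CountMatrix,
    target_cluster: str,
    criterion: MarkerCriterion = MarkerCriterion(),
    normalized: np.ndarray | None = None,
) -> list[MarkerResult]:
    """Test every gene for marker status in ``target_cluster`` vs the rest.

    The expressing-fraction gate applies to the target cluster only. Pass a
    precomputed ``normalized`` matrix (from :func:`normalize_counts`) to
    amortize normalization across clusters.
    """
    clusters = matrix.cells["cluster"].to_numpy()
    available = sorted(set(clusters))
    if target_cluster not in available:
        raise ValueError(
            f"cluster {target_cluster!r} not found; available: {available}"
        )
    idx_t = np.flatnonzero(clusters == target_cluster)
    idx_r = np.flatnonzero(clusters != target_cluster)
    if len(idx_t) < 3:
        raise ValueError(f"cluster {target_cluster!r} has fewer than 3 cells")
    if normalized is None:
        normalized = normalize_counts(matrix)
    return _test_groups(matrix, normalized, idx_t, idx_r, criterion, pct_rule="target")


@dataclass(frozen=True)
class ConditionDEGResult:
    """Condition-vs-condition DE within one cluster: full table + passing lists."""

    results: tuple[MarkerResult, ...]
    up: tuple[MarkerResult, ...]
    down: tuple[MarkerResult, ...]


def condition_deg(
    matrix: CountMatrix,
    cluster: str,
    condition_pair: tuple[str, str],
    criterion: MarkerCriterion = MarkerCriterion(),
    normalized: np.ndarray | None = None,
) -> ConditionDEGResult:
    """Differential expression between two conditions inside one cluster.

    ``condition_pair`` is (reference, test); fold is test/reference, so
    'up' means upregulated in the test condition. The expressing-fraction
    gate uses the larger of the two group fractions, which makes the result
    exactly antisymmetric under swapping the pair (up and down lists
    exchange, folds invert).
    """
    ref, test = condition_pair
    cells = matrix.cells
    in_cluster = (cells["cluster"] == cluster).to_numpy()
    if not in_cluster.any():
        available = sorted(set(cells["cluster"]))
        raise ValueError(f"cluster {cluster!r} not found; available: {available}")
    cond = cells["condition"].to_numpy()
    idx_t = np.flatnonzero(in_cluster & (cond == test))
    idx_r = np.flatnonzero(in_cluster & (cond == ref))
    for label, idx in ((test, idx_t), (ref, idx_r)):
        if len(idx) < 3:
            raise ValueError(
                f"condition {label!r} has fewer than 3 cells in cluster {cluster!r}"
            )
    if normalized is None:
        normalized = normalize_counts(matrix)
    results = _test_groups(matrix, normalized, idx_t, idx_r, criterion, pct_rule="either")
    up = tuple(r for r in results if r.passes and r.direction == "up")
    down = tuple(r for r in results if r.passes and r.direction == "down")
    return ConditionDEGResult(results=tuple(results), up=up, down=down)


def markers_table(results: Sequence[MarkerResult], bh_fdr: bool = False) -> pd.DataFrame:
    """Tabulate marker results; optionally append BH-adjusted q-values."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "fold_change": [r.fold_change for r in results],
            "pct_target": [r.pct_target for r in results],
            "pct_rest": [r.pct_rest for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "passes": [r.passes for r in results],
        }
    )
    if bh_fdr:
        df["q_value"] = stats.false_discovery_control(df["p_value"].to_numpy())
    return df
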