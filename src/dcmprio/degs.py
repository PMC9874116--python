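"""Differential expression between cases and controls on the training split.

A gene is declared differentially expressed when |log2 fold change| > 1
(strict) and its Benjamini-Hochberg adjusted p-value is < 0.001 (strict).
The log2 fold change is oriented case minus control, so positive means
up-regulated in cases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

WELCH_T = "welch_t"
WILCOXON = "wilcoxon"

_EQ_TOL = 1e-12


def _class_blocks(matrix: pd.DataFrame, annotation: pd.DataFrame):
    samples = matrix.columns
    labels = annotation.loc[samples, "label"]
    case_cols = samples[(labels == "case").to_numpy()]
    ctrl_cols = samples[(labels == "control").to_numpy()]
    if len(case_cols) == 0 or len(ctrl_cols) == 0:
        raise ValueError("both classes must be present")
    return matrix[case_cols].to_numpy(float), matrix[ctrl_cols].to_numpy(float)


def gene_logfc(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Per-gene log2 fold change: mean(case) - mean(control)."""
    case, ctrl = _class_blocks(matrix, annotation)
    return pd.Series(case.mean(axis=1) - ctrl.mean(axis=1),
                     index=matrix.index, name="logFC")


def gene_test(matrix: pd.DataFrame, annotation: pd.DataFrame,
              method: str = WELCH_T) -> pd.Series:
    """Two-sided per-gene p-values for a case/control difference.

    ``welch_t`` uses the unequal-variance t-test; ``wilcoxon`` the
    Mann-Whitney rank-sum test (exact for small tie-free samples). Genes
    that are constant across both classes get p = 1 by convention (p = 0
    for the degenerate zero-variance case with unequal class means under
    the t-test).
    """
    case, ctrl = _class_blocks(matrix, annotation)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need at least 2 samples per class")
    if method == WELCH_T:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        bad = ~np.isfinite(p)
        if bad.any():
            diff = case.mean(axis=1) - ctrl.mean(axis=1)
            p[bad] = np.where(np.abs(diff[bad]) < _EQ_TOL, 1.0, 0.0)
    elif method == WILCOXON:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.mannwhitneyu(case, ctrl, axis=1,
                                     alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
        both = np.concatenate([case, ctrl], axis=1)
        constant = np.ptp(both, axis=1) < _EQ_TOL
        # fully tied rows have zero rank variance; p = 1 by convention
        p[constant | ~np.isfinite(p)] = 1.0
    else:
        raise ValueError(f"unknown test method {method!r}")
    return pd.Series(np.clip(p, 0.0, 1.0), index=matrix.index, name="p_raw")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj(i) = min over ranks j >= rank(i) of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def deg_table(matrix: pd.DataFrame, annotation: pd.DataFrame,
              logfc_threshold: float = 1.0, fdr_threshold: float = 0.001,
              method: str = WELCH_T) -> pd.DataFrame:
    """Full per-gene record table (all genes, passing or not).

    Columns: logFC, p_raw, fdr, direction (up/down), passes. Both
    thresholds are strict, matching the selection rule |logFC| > 1 and
    FDR < 0.001.
    """
    logfc = gene_logfc(matrix, annotation)
    p_raw = gene_test(matrix, annotation, method=method)
    fdr = benjamini_hochberg(p_raw.to_numpy())
    records = pd.DataFrame({
        "logFC": logfc,
        "p_raw": p_raw,
        "fdr": fdr,
    })
    records["direction"] = np.where(records["logFC"] > 0, "up", "down")
    records["passes"] = (records["logFC"].abs() > logfc_threshold) & (
        records["fdr"] < fdr_threshold
    )
    records.index.name = "gene_id"
    return records


def select_degs(records: pd.DataFrame) -> pd.DataFrame:
    """Passing genes, sorted by fdr ascending then |logFC| descending."""
    passing = records[records["passes"]].copy()
    passing["_abs"] = passing["logFC"].abs()
    passing = passing.sort_values(by=["fdr", "_abs"],
                                  ascending=[True, False], kind="mergesort")
    return passing.drop(columns="_abs")
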