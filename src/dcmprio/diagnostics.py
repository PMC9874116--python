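"""Per-gene diagnostic evaluation: ROC/AUC and group comparisons.

The AUC is computed through the Mann-Whitney rank identity with tie
correction — the probability that a random case sample outranks a random
control sample, ties counting one half — and the ROC curve itself comes
from the standard cumulative true/false-positive construction. Because
candidate genes may be either up- or down-regulated, the orientation is
auto-selected so the reported AUC is >= 0.5 and the chosen direction
(case_higher / case_lower) is recorded rather than discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

CASE_HIGHER = "case_higher"
CASE_LOWER = "case_lower"


@dataclass
class ROCRecord:
    gene_id: str
    split: str
    auc: float
    direction: str
    curve: np.ndarray  # (k, 2) array of (1 - specificity, sensitivity)


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = (y == "case").astype(int)
    return y.astype(int)


def mann_whitney_auc(values, labels) -> float:
    """AUC via average ranks: (R_case - n1(n1+1)/2) / (n1 * n0)."""
    x = np.asarray(values, dtype=float)
    y = _binary_labels(labels)
    n1 = int(y.sum())
    n0 = int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(x)
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def gene_roc(values, labels, gene_id: str = "", split: str = "train") -> ROCRecord:
    """ROC record for one gene on one split, orientation auto-selected.

    Requires both classes with at least 2 samples each. The stored curve
    starts at (0, 0), ends at (1, 1) and is monotone in both coordinates;
    its trapezoidal area equals the rank-based AUC.
    """
    x = np.asarray(values, dtype=float)
    y = _binary_labels(labels)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    auc = mann_whitney_auc(x, y)
    if auc >= 0.5:
        direction, scores, auc_out = CASE_HIGHER, x, auc
    else:
        direction, scores, auc_out = CASE_LOWER, -x, 1.0 - auc
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    curve = np.column_stack([fpr, tpr])
    return ROCRecord(gene_id=gene_id, split=split, auc=auc_out,
                     direction=direction, curve=curve)


def compare_groups(values, labels, method: str = "auto") -> dict:
    """Two-sided case/control comparison with per-group summaries.

    ``auto`` routes to Welch's t-test when a Shapiro-Wilk test (alpha =
    0.05) does not reject normality in either group, else to the
    Mann-Whitney rank-sum test. Identical groups give p = 1.
    """
    x = np.asarray(values, dtype=float)
    y = _binary_labels(labels)
    case = x[y == 1]
    ctrl = x[y == 0]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both classes must be present")
    summaries = {
        "case_mean": float(case.mean()), "case_sd": float(case.std(ddof=1)),
        "control_mean": float(ctrl.mean()), "control_sd": float(ctrl.std(ddof=1)),
        "n_case": len(case), "n_control": len(ctrl),
    }
    if np.ptp(x) == 0:
        return {"p": 1.0, "method": "degenerate", **summaries}
    if method == "auto":
        normal = True
        for grp in (case, ctrl):
            if len(grp) >= 3 and np.ptp(grp) > 0:
                if stats.shapiro(grp).pvalue < 0.05:
                    normal = False
        method = "welch_t" if normal else "wilcoxon"
    if method == "welch_t":
        p = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
    elif method == "wilcoxon":
        p = float(stats.mannwhitneyu(case, ctrl, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(p):
        p = 1.0
    return {"p": p, "method": method, **summaries}


def evaluate_candidates(matrix: pd.DataFrame, annotation: pd.DataFrame,
                        genes) -> tuple:
    """ROC records for each candidate gene on both splits plus test-split
    group comparisons; returns (roc DataFrame, curves dict, tests DataFrame)."""
    ann = annotation.loc[matrix.columns]
    roc_rows, curves, test_rows = [], {}, []
    for split in ("train", "test"):
        cols = ann.index[(ann["split"] == split).to_numpy()]
        if len(cols) == 0:
            continue
        labels = ann.loc[cols, "label"].to_numpy()
        for g in genes:
            rec = gene_roc(matrix.loc[g, cols], labels, gene_id=g, split=split)
            roc_rows.append({"gene_id": g, "split": split, "auc": rec.auc,
                             "direction": rec.direction})
            curves[(g, split)] = rec.curve
    test_cols = ann.index[(ann["split"] == "test").to_numpy()]
    if len(test_cols) > 0:
        labels = ann.loc[test_cols, "label"].to_numpy()
        for g in genes:
            res = compare_groups(matrix.loc[g, test_cols], labels)
            test_rows.append({"gene_id": g, **res})
    return pd.DataFrame(roc_rows), curves, pd.DataFrame(test_rows)
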