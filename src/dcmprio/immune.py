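"""Correlation of candidate-gene expression with immune-cell fractions.

Fractions are an input (any deconvolution output in the usual samples x
cell-types tabular layout with rows summing to 1); the deconvolution
itself is out of scope. Per (gene, cell type) pair a Pearson coefficient
with its t-distribution p-value (n - 2 degrees of freedom) is reported.
No multiple-testing correction is applied to the pair p-values; consumers
filtering at a nominal alpha should keep that in mind.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

_ROW_SUM_TOL = 1e-6


def correlate(expression: pd.DataFrame, fractions: pd.DataFrame,
              genes) -> pd.DataFrame:
    """Pearson correlation records for every (gene, cell type) pair.

    Uses the samples common to both matrices (at least 3 required).
    Fraction rows must sum to 1 within 1e-6. Zero-variance cell types (or
    genes) yield r = 0, p = 1 and are flagged degenerate.
    """
    common = expression.columns.intersection(fractions.index)
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 common samples, found {len(common)}"
        )
    frac = fractions.loc[common]
    sums = frac.sum(axis=1).to_numpy()
    if np.max(np.abs(sums - 1.0)) > _ROW_SUM_TOL:
        raise ValueError("fraction rows must sum to 1 (within 1e-6)")
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise ValueError(f"genes missing from expression matrix: {missing}")

    n = len(common)
    rows = []
    for g in genes:
        x = expression.loc[g, common].to_numpy(float)
        x_sd = x.std()
        for ct in frac.columns:
            f = frac[ct].to_numpy(float)
            if x_sd == 0 or f.std() == 0:
                rows.append({"gene_id": g, "cell_type": ct, "r": 0.0,
                             "p": 1.0, "n": n, "degenerate": True})
                continue
            r, p = stats.pearsonr(x, f)
            rows.append({"gene_id": g, "cell_type": ct, "r": float(r),
                         "p": float(p), "n": n, "degenerate": False})
    return pd.DataFrame(rows)


def significance_filter(records: pd.DataFrame,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Records with p < alpha, sorted by |r| descending."""
    if records.empty:
        return records.copy()
    kept = records[records["p"] < alpha].copy()
    kept["_abs_r"] = kept["r"].abs()
    kept = kept.sort_values("_abs_r", ascending=False, kind="mergesort")
    return kept.drop(columns="_abs_r")
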