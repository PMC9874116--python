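"""Overall-weight fusion of heterogeneous model importances.

The core statistic: for each model family f with raw per-gene weights
w_f(g), the normalized weight is |w_f(g)| / max_g' |w_f(g')|, and a gene's
overall weight is the sum of its normalized weights across the six
families:

    overall(g) = sum_f |w_f(g)| / max|w_f|        in [0, 6]

The statistic is invariant to rescaling any single family's raw weights by
a positive constant and to sign flips, so coefficients, hyperplane
weights, impurity decreases and connection-weight contributions are
directly comparable. Candidate genes are those with overall weight
strictly greater than 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import FAMILIES, ImportanceVector

# display order and labels used by the report table
REPORT_COLUMNS = (("lasso", "LASSO"), ("random_forest", "RF"),
                  ("neural_net", "NN"), ("gbm", "GBM"),
                  ("decision_tree", "DT"), ("svm_linear", "SVM"))


@dataclass
class NormalizedWeightTable:
    """Gene x family matrix of max-|w|-normalized weights plus row sums.

    ``normalized`` has one column per family with max exactly 1 (all-zero
    columns belong to ``degenerate`` families and contribute 0);
    ``max_abs`` holds the per-family denominators; ``overall`` the per-gene
    sums.
    """

    normalized: pd.DataFrame
    max_abs: pd.Series
    overall: pd.Series
    degenerate: frozenset


def _as_series_map(importances) -> dict:
    if isinstance(importances, Mapping):
        out = {}
        for fam, v in importances.items():
            out[fam] = v.weights if isinstance(v, ImportanceVector) else pd.Series(v)
        return out
    out = {}
    for iv in importances:
        out[iv.family] = iv.weights
    return out


def normalize_weights(
    importances: Union[Mapping, Iterable[ImportanceVector]],
    families: Optional[Sequence[str]] = None,
) -> NormalizedWeightTable:
    """Normalize each family's weights by its max |w| and sum per gene.

    Requires exactly the six canonical families unless ``families``
    explicitly overrides the set (logged as a warning, since the [0, 6]
    scale and the > 1 selection threshold presuppose six terms). All
    vectors must cover the same gene set. A family whose weights are all
    zero yields an all-zero column, is recorded as degenerate and
    contributes 0 to every sum.
    """
    series = _as_series_map(importances)
    if families is None:
        if set(series) != set(FAMILIES):
            raise ValueError(
                f"expected exactly the six families {sorted(FAMILIES)}, "
                f"got {sorted(series)}; pass families=... to override"
            )
        families = [f for f in FAMILIES if f in series]
    else:
        families = list(families)
        if set(families) != set(series):
            raise ValueError("families override does not match importances")
        if set(families) != set(FAMILIES):
            warnings.warn(
                f"fusing {len(families)} families instead of the canonical "
                f"six; the overall-weight scale is [0, {len(families)}]"
            )

    genes = series[families[0]].index
    for fam in families[1:]:
        if not series[fam].index.equals(genes):
            a = set(genes)
            b = set(series[fam].index)
            raise ValueError(
                f"gene sets differ between families "
                f"({families[0]!r} vs {fam!r}): "
                f"{sorted(a.symmetric_difference(b))[:5]}"
            )

    normalized = {}
    max_abs = {}
    degenerate = set()
    for fam in families:
        w = series[fam].to_numpy(dtype=float)
        m = float(np.max(np.abs(w))) if w.size else 0.0
        max_abs[fam] = m
        if m == 0.0:
            degenerate.add(fam)
            normalized[fam] = np.zeros_like(w)
        else:
            normalized[fam] = np.abs(w) / m
    table = pd.DataFrame(normalized, index=genes, columns=list(families))
    table.index.name = "gene_id"
    overall = table.sum(axis=1)
    overall.name = "overall"
    return NormalizedWeightTable(
        normalized=table,
        max_abs=pd.Series(max_abs, name="max_abs"),
        overall=overall,
        degenerate=frozenset(degenerate),
    )


def select_candidates(table: NormalizedWeightTable,
                      threshold: float = 1.0) -> pd.Series:
    """Genes with overall weight strictly above ``threshold``, sorted by
    overall weight descending; ties break lexicographically by gene id."""
    passing = table.overall[table.overall > threshold]
    order = sorted(passing.index, key=lambda g: (-passing[g], g))
    return passing.loc[order]


def weight_table_report(table: NormalizedWeightTable):
    """Report tables in the conventional column order
    (LASSO, RF, NN, GBM, DT, SVM, Sum).

    Returns ``(display, full)``: the display table rounds to 2 decimals
    while the full-precision twin keeps every digit; the Sum column is the
    full-precision row sum in both (rounded only for display), so a
    displayed Sum can differ by up to 0.01 from the sum of its displayed
    row entries.
    """
    full = pd.DataFrame(index=table.normalized.index)
    for fam, label in REPORT_COLUMNS:
        if fam in table.normalized.columns:
            full[label] = table.normalized[fam]
    full["Sum"] = table.overall
    full = full.sort_values("Sum", ascending=False, kind="mergesort")
    display = full.round(2)
    return display, full
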