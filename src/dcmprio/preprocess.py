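"""Merging-cohort preprocessing: probe averaging, quantile normalization,
location-scale batch adjustment, and batch-level train/test splitting.

Pipeline order is fixed: duplicate-probe averaging -> log2 (only if the
input is linear scale) -> quantile normalization -> batch adjustment ->
split. Quantile normalization and batch adjustment are idempotent (to 1e-9)
and no step reorders samples.
"""

from __future__ import annotations

import itertools
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

TRAIN = "train"
TEST = "test"
UNASSIGNED = "unassigned"

_MAX_BATCHES_EXHAUSTIVE = 20


def average_duplicate_probes(matrix: pd.DataFrame,
                             probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probe rows to one row per gene by arithmetic mean.

    Gene order in the output is lexicographic. Raises on an empty matrix or
    probes missing from the map.
    """
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    missing = matrix.index.difference(probe_to_gene.index)
    if len(missing) > 0:
        raise ValueError(f"probes missing from probe->gene map: {list(missing)[:5]}")
    genes = probe_to_gene.loc[matrix.index]
    out = matrix.groupby(genes.to_numpy()).mean()
    out = out.sort_index()
    out.index.name = "gene_id"
    return out


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount) for linear-scale input matrices."""
    if (matrix.to_numpy() + pseudocount <= 0).any():
        raise ValueError("values must be > -pseudocount for log2 transform")
    return np.log2(matrix + pseudocount)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common distribution of mean order
    statistics.

    Tied values within a column receive the mean of the reference values at
    their tied ranks (average-rank convention), so the map is deterministic.
    """
    X = matrix.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    ranks = rankdata(X, axis=0)  # average ranks for ties
    normalized = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns)


def adjust_batches(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Remove per-gene batch location/scale differences.

    Every batch is standardized, per gene, to the grand mean and to the
    pooled within-batch standard deviation (sqrt of sum((n_b - 1) s_b^2) /
    (N - B)); this exact location-scale form is idempotent. Genes with zero
    variance inside a batch get a location-only shift there.
    """
    samples = matrix.columns
    batches = annotation.loc[samples, "batch"]
    counts = batches.value_counts()
    single = counts[counts < 2]
    if len(single) > 0:
        raise ValueError(f"batch {single.index[0]!r} has fewer than 2 samples")
    X = matrix.to_numpy(dtype=float)
    grand_mean = X.mean(axis=1)

    batch_ids = counts.index.tolist()
    n_total = X.shape[1]
    n_b = {b: int(counts[b]) for b in batch_ids}
    col_idx = {b: np.flatnonzero((batches == b).to_numpy()) for b in batch_ids}

    # pooled within-batch variance (ddof=1 per batch)
    ss_within = np.zeros(X.shape[0])
    stats = {}
    for b in batch_ids:
        sub = X[:, col_idx[b]]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        stats[b] = (m, v)
        ss_within += (n_b[b] - 1) * v
    pooled_sd = np.sqrt(ss_within / (n_total - len(batch_ids)))

    out = np.empty_like(X)
    for b in batch_ids:
        m, v = stats[b]
        sub = X[:, col_idx[b]]
        centered = sub - m[:, None]
        s = np.sqrt(v)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(s > 0, pooled_sd / np.where(s > 0, s, 1.0), 1.0)
        out[:, col_idx[b]] = centered * factor[:, None] + grand_mean[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def split_batches(annotation: pd.DataFrame, ratio: float = 5.0,
                  seed: Optional[int] = None) -> pd.DataFrame:
    """Assign whole batches to train or test so the train:test sample ratio
    is as close to ``ratio`` as any batch-level partition allows.

    Both classes must be present in both splits; partitions violating this
    are discarded. All 2^B partitions are enumerated (B <= 20); ties on the
    ratio objective break lexicographically on the sorted train-batch
    tuple, so the result is deterministic. ``seed`` is accepted for
    interface symmetry with the other stages.
    """
    batches = sorted(annotation["batch"].unique())
    B = len(batches)
    if B < 2:
        raise ValueError("batch-level splitting needs at least 2 batches")
    if B > _MAX_BATCHES_EXHAUSTIVE:
        raise ValueError(f"too many batches ({B}) for exhaustive partitioning")

    sizes = {}
    for b in batches:
        sub = annotation[annotation["batch"] == b]
        sizes[b] = (
            len(sub),
            int((sub["label"] == "control").sum()),
            int((sub["label"] == "case").sum()),
        )

    best = None
    for r in range(1, B):
        for train_set in itertools.combinations(batches, r):
            train = set(train_set)
            n_train = sum(sizes[b][0] for b in train)
            n_test = sum(sizes[b][0] for b in batches if b not in train)
            if n_test == 0 or n_train == 0:
                continue
            ctrl_train = sum(sizes[b][1] for b in train)
            case_train = sum(sizes[b][2] for b in train)
            ctrl_test = sum(sizes[b][1] for b in batches if b not in train)
            case_test = sum(sizes[b][2] for b in batches if b not in train)
            if min(ctrl_train, case_train, ctrl_test, case_test) == 0:
                continue
            obj = abs(n_train / n_test - ratio)
            key = (obj, tuple(sorted(train)))
            if best is None or key < best[0]:
                best = (key, train)
    if best is None:
        raise ValueError(
            "no batch partition has both classes in both train and test"
        )
    train = best[1]
    out = annotation.copy()
    out["split"] = [TRAIN if b in train else TEST for b in out["batch"]]
    return out


def preprocess_pipeline(matrix: pd.DataFrame, probe_to_gene: pd.Series,
               annotation: pd.DataFrame, ratio: float = 5.0,
               linear_scale: bool = False,
               seed: Optional[int] = None):
    """Run the full preprocessing chain; returns (gene matrix, annotation)."""
    gene_matrix = average_duplicate_probes(matrix, probe_to_gene)
    if linear_scale:
        gene_matrix = log2_transform(gene_matrix)
    gene_matrix = quantile_normalize(gene_matrix)
    gene_matrix = adjust_batches(gene_matrix, annotation)
    split_ann = split_batches(annotation, ratio=ratio, seed=seed)
    return gene_matrix, split_ann
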