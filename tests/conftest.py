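"""Shared fixtures: one reference synthetic dataset carried through the
pipeline stages, fitted once per session."""

import numpy as np
import pandas as pd
import pytest

from dcmprio import degs, models, synthetic
from dcmprio.preprocess import preprocess_pipeline


@pytest.fixture(scope="session")
def demo_config():
    return synthetic.default_config(seed=11)


@pytest.fixture(scope="session")
def demo_dataset(demo_config):
    return synthetic.generate_dataset(demo_config)


@pytest.fixture(scope="session")
def preprocessed(demo_dataset):
    gene_matrix, annotation = preprocess_pipeline(
        demo_dataset.matrix, demo_dataset.probe_to_gene,
        demo_dataset.annotation, seed=0,
    )
    return gene_matrix, annotation


@pytest.fixture(scope="session")
def deg_records(preprocessed):
    gene_matrix, annotation = preprocessed
    train_cols = annotation.index[annotation["split"] == "train"]
    return degs.deg_table(gene_matrix[train_cols], annotation)


@pytest.fixture(scope="session")
def deg_passing(deg_records):
    return degs.select_degs(deg_records)


@pytest.fixture(scope="session")
def fitted_suite(preprocessed, deg_passing):
    """All six families fitted on the DEG-restricted demo data (no CV)."""
    gene_matrix, annotation = preprocessed
    fitted, importances, performance = models.fit_all_models(
        gene_matrix.loc[deg_passing.index], annotation,
        seed=11, compute_cv=False,
    )
    return fitted, importances, performance


@pytest.fixture()
def two_class_toy():
    """Tiny single-batch two-class matrix: gene T0 separates perfectly."""
    rng = np.random.default_rng(42)
    n = 30
    values = rng.normal(0.0, 1.0, (8, 2 * n))
    values[0] = np.concatenate(
        [rng.normal(0.0, 0.3, n), rng.normal(6.0, 0.3, n)]
    )
    matrix = pd.DataFrame(
        values,
        index=[f"T{i}" for i in range(8)],
        columns=[f"S{j:02d}" for j in range(2 * n)],
    )
    annotation = pd.DataFrame(
        {"label": ["control"] * n + ["case"] * n,
         "batch": "B1", "split": "train"},
        index=matrix.columns,
    )
    return matrix, annotation
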