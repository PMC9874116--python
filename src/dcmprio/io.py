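"""Plain-text TSV readers/writers for every pipeline artifact.

Probe-level expression: first column ``probe_id``, second ``gene_id``,
remaining columns samples. Gene-level expression: ``gene_id`` then
samples. Annotation: ``sample_id``, ``label``, ``batch``, ``split``.
Fractions: ``sample_id`` then one column per cell type (trailing
deconvolution summary columns such as P-value / Correlation / RMSE are
dropped with a warning).
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import pandas as pd

_CIBERSORT_EXTRAS = ("P-value", "Correlation", "RMSE", "Absolute score")


def write_probe_matrix(matrix: pd.DataFrame, probe_to_gene: pd.Series,
                       path) -> None:
    out = matrix.copy()
    out.insert(0, "gene_id", probe_to_gene.loc[out.index])
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_probe_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    probe_to_gene = df["gene_id"]
    return df.drop(columns="gene_id"), probe_to_gene


def write_gene_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "split" not in ann.columns:
        ann["split"] = "unassigned"
    return ann


def write_fractions(fractions: pd.DataFrame, path) -> None:
    fractions.to_csv(path, sep="\t", index_label="sample_id")


def read_fractions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    extras = [c for c in df.columns if c in _CIBERSORT_EXTRAS]
    if extras:
        warnings.warn(f"dropping deconvolution summary columns: {extras}")
        df = df.drop(columns=extras)
    df.index.name = "sample_id"
    return df


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
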