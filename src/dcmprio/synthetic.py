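"""Synthetic multi-batch two-class expression data with planted effects.

Generates log2-scale gene-by-sample intensity matrices that mimic merged
microarray cohorts: several batches (one per source array), a control and a
case group per batch, per-gene additive batch offsets, per-gene
multiplicative batch noise-scale factors, Gaussian measurement noise, a
configurable set of planted differentially expressed genes (both signs),
duplicate probes mapping to one gene, and an optional per-sample
immune-cell-fraction matrix with tunable gene/cell-type correlations.

Intensities are drawn directly on the log2 scale so planted effects are
additive log2 fold changes. A single global seed feeds one hierarchical RNG
stream per batch (plus streams for gene-level baselines and duplicate-probe
noise), so the same config always reproduces the same dataset byte for byte
and batch streams do not shift when unrelated config fields change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"

# Spread of per-gene baseline log2 intensity around ``baseline_mean``;
# typical across-gene spread of log2 microarray intensities.
BASELINE_GENE_SD = 2.0

# Concentration of cell-fraction variability on the log scale.
_FRACTION_LOG_SD = 0.4


@dataclass(frozen=True)
class SynthConfig:
    """Recipe for one synthetic multi-batch expression dataset.

    Parameters
    ----------
    n_genes
        Number of distinct genes.
    samples_per_batch
        One ``(n_control, n_case)`` pair per batch.
    planted
        ``(gene_index, log2_effect)`` pairs; the effect is added to case
        samples, so its sign encodes direction (positive = up in cases).
    batch_shift_sd
        SD of the per-gene additive batch offset (log2 units).
    batch_scale_sd
        SD (log scale) of the per-gene multiplicative factor applied to the
        noise term within a batch.
    noise_sd
        SD of per-measurement Gaussian noise (log2 units).
    baseline_mean
        Center of per-gene baseline log2 intensities.
    duplicate_probe_fraction
        Fraction of genes that receive a second probe row (same signal,
        independent noise).
    seed
        Global seed; hierarchically split into per-batch streams.
    """

    n_genes: int
    samples_per_batch: tuple
    planted: tuple = ()
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.1
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    duplicate_probe_fraction: float = 0.0
    seed: int = 0

    @property
    def n_batches(self) -> int:
        return len(self.samples_per_batch)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_batches == 0:
            raise ValueError("at least one batch is required")
        for pair in self.samples_per_batch:
            if len(pair) != 2 or any(int(n) < 0 for n in pair):
                raise ValueError(
                    f"samples_per_batch entries must be (n_control, n_case) "
                    f"pairs of non-negative counts, got {pair!r}"
                )
        idx = [int(g) for g, _ in self.planted]
        if len(set(idx)) != len(idx):
            raise ValueError("planted gene indices must be unique")
        if any(g < 0 or g >= self.n_genes for g in idx):
            raise ValueError("planted gene indices must be in [0, n_genes)")
        if self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ValueError("batch effect SDs must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.duplicate_probe_fraction < 1.0):
            raise ValueError("duplicate_probe_fraction must be in [0, 1)")


@dataclass
class SyntheticDataset:
    """A generated dataset: probe-level matrix plus ground truth.

    ``matrix`` is probes x samples (log2 scale); ``probe_to_gene`` maps each
    probe row to its gene; ``annotation`` is indexed by sample id with
    ``label``, ``batch`` and ``split`` columns; ``truth`` lists the planted
    ``(gene_id, log2_effect)`` pairs; ``fractions`` (samples x cell types,
    rows summing to 1) is filled in by :func:`generate_fractions`.
    """

    matrix: pd.DataFrame
    probe_to_gene: pd.Series
    annotation: pd.DataFrame
    truth: tuple
    fractions: Optional[pd.DataFrame] = None


def gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate a multi-batch two-class dataset from ``config``.

    With ``noise_sd = 0`` and both batch SDs 0 the case-minus-control
    difference of every planted gene equals its log2 effect exactly and all
    non-planted genes have difference 0.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(2 + config.n_batches)
    gene_rng = np.random.default_rng(streams[0])
    dup_rng = np.random.default_rng(streams[1])

    n_genes = config.n_genes
    baseline = config.baseline_mean + gene_rng.normal(0.0, BASELINE_GENE_SD, n_genes)
    effect = np.zeros(n_genes)
    for g, e in config.planted:
        effect[int(g)] = float(e)

    blocks = []          # per-batch primary-probe value blocks
    signal_blocks = []   # noise-free signal, reused for duplicate probes
    scale_blocks = []
    labels, batches, sample_ids = [], [], []
    for b, (n_ctrl, n_case) in enumerate(config.samples_per_batch):
        n_ctrl, n_case = int(n_ctrl), int(n_case)
        rng = np.random.default_rng(streams[2 + b])
        shift = rng.normal(0.0, 1.0, n_genes) * config.batch_shift_sd
        scale = np.exp(rng.normal(0.0, 1.0, n_genes) * config.batch_scale_sd)
        ncol = n_ctrl + n_case
        case_ind = np.concatenate([np.zeros(n_ctrl), np.ones(n_case)])
        signal = (
            baseline[:, None]
            + effect[:, None] * case_ind[None, :]
            + shift[:, None]
        )
        noise = rng.normal(0.0, 1.0, (n_genes, ncol)) * config.noise_sd
        blocks.append(signal + scale[:, None] * noise)
        signal_blocks.append(signal)
        scale_blocks.append(scale)
        batch_id = f"B{b + 1}"
        for j in range(ncol):
            sample_ids.append(f"{batch_id}_S{j + 1:03d}")
            labels.append(CONTROL if j < n_ctrl else CASE)
            batches.append(batch_id)

    values = np.concatenate(blocks, axis=1)
    genes = [gene_name(i) for i in range(n_genes)]
    probe_ids = [f"{g}_p1" for g in genes]
    probe_gene = list(genes)

    n_dup = int(round(config.duplicate_probe_fraction * n_genes))
    if n_dup > 0:
        dup_idx = np.sort(dup_rng.choice(n_genes, size=n_dup, replace=False))
        signal_all = np.concatenate([s[dup_idx] for s in signal_blocks], axis=1)
        n_total = values.shape[1]
        dup_noise = dup_rng.normal(0.0, 1.0, (n_dup, n_total)) * config.noise_sd
        offset = 0
        scaled = np.empty_like(dup_noise)
        for s_blk, blk in zip(scale_blocks, blocks):
            w = blk.shape[1]
            scaled[:, offset:offset + w] = (
                s_blk[dup_idx][:, None] * dup_noise[:, offset:offset + w]
            )
            offset += w
        values = np.concatenate([values, signal_all + scaled], axis=0)
        probe_ids += [f"{genes[i]}_p2" for i in dup_idx]
        probe_gene += [genes[i] for i in dup_idx]

    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=pd.Index(sample_ids, name="sample_id"))
    probe_to_gene = pd.Series(probe_gene, index=matrix.index, name="gene_id")
    annotation = pd.DataFrame(
        {"label": labels, "batch": batches, "split": "unassigned"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = tuple((genes[int(g)], float(e)) for g, e in config.planted)
    return SyntheticDataset(matrix=matrix, probe_to_gene=probe_to_gene,
                            annotation=annotation, truth=truth)


def generate_fractions(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    n_cell_types: int = 22,
    linked: Sequence[tuple] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-sample immune-cell fractions (rows sum to 1).

    Each cell type gets a log-normal latent abundance per sample; for every
    ``(gene_id, cell_type_index, target_r)`` triple in ``linked`` the latent
    of that cell type is blended with the standardized expression of the gene
    so that the resulting fraction correlates with the gene (same sign as
    ``target_r``; the normalization across cell types attenuates the
    magnitude slightly).

    Parameters mirror the deconvolution-output layout downstream stages
    consume: samples x cell types, non-negative, rows summing to 1.
    """
    if n_cell_types < 2:
        raise ValueError("n_cell_types must be at least 2")
    for gene, c, r in linked:
        if not (-1.0 < float(r) < 1.0):
            raise ValueError(f"target_r must be in (-1, 1), got {r}")
        if not (0 <= int(c) < n_cell_types):
            raise ValueError(f"cell type index {c} out of range")
        if gene not in expression.index:
            raise ValueError(f"linked gene {gene!r} not in expression matrix")

    samples = list(annotation.index)
    n = len(samples)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mu = rng.normal(0.0, 0.5, n_cell_types)
    z = rng.normal(0.0, 1.0, (n, n_cell_types))
    for gene, c, r in linked:
        r = float(r)
        x = expression.loc[gene, samples].to_numpy(float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"linked gene {gene!r} has zero variance")
        xs = (x - x.mean()) / sd
        z[:, int(c)] = r * xs + np.sqrt(1.0 - r * r) * z[:, int(c)]
    raw = np.exp(mu[None, :] + _FRACTION_LOG_SD * z)
    fractions = raw / raw.sum(axis=1, keepdims=True)
    cols = [f"CellType{c + 1:02d}" for c in range(n_cell_types)]
    return pd.DataFrame(fractions, index=pd.Index(samples, name="sample_id"),
                        columns=cols)


def default_config(seed: int = 0, n_genes: int = 500) -> SynthConfig:
    """The package's reference study conditions.

    Six batches emulating a merged multi-array cohort: two large arrays
    (train side, 160 samples) and four small ones (test side, 32 samples),
    an exact 5:1 batch-level split. Twenty planted genes — 3 strong
    (|log2FC| = 3.0) and 17 moderate (|log2FC| = 1.4), mixed signs — so the
    differential-expression stage passes ~20 genes of which three dominate.
    """
    strong = ((10, 3.0), (20, -3.0), (30, 3.0))
    moderate = tuple(
        (60 + 25 * k, 1.4 if k % 2 == 0 else -1.4) for k in range(17)
    )
    if n_genes <= 60 + 25 * 16:
        raise ValueError("default planted layout needs n_genes > 460")
    return SynthConfig(
        n_genes=n_genes,
        samples_per_batch=((40, 44), (36, 40), (5, 4), (4, 4), (4, 3), (4, 4)),
        planted=strong + moderate,
        batch_shift_sd=0.5,
        batch_scale_sd=0.1,
        noise_sd=0.5,
        baseline_mean=8.0,
        duplicate_probe_fraction=0.1,
        seed=seed,
    )


def strong_planted(config: SynthConfig, threshold: float = 2.0) -> tuple:
    """Gene ids of planted effects with |log2FC| above ``threshold``."""
    return tuple(
        gene_name(int(g)) for g, e in config.planted if abs(float(e)) > threshold
    )
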