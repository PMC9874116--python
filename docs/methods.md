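# Methods

## The statistic

For each classifier family *f* fitted on the training split restricted
to differentially expressed genes, the adapter extracts one raw weight
per gene, w_f(g): the logistic-LASSO coefficient at the CV-selected
penalty, the linear-SVM primal hyperplane weight, the CART total
impurity decrease over the feature's splits, the random-forest mean
impurity-decrease importance, the boosting relative influence (summed
gain), and a Garson-style absolute connection-weight contribution for
the neural network. The fusion statistic is

    overall(g) = Σ_f |w_f(g)| / max_g' |w_f(g')|

so each family contributes on a common [0, 1] scale regardless of its
native units. Properties relied on throughout: overall ∈ [0, F] with F
the number of non-degenerate families (six by default); invariance to
rescaling any one family's weights by c > 0; invariance to sign flips.
Candidates are genes with overall weight **strictly** greater than 1 —
intuitively, genes that accumulate more evidence than a single family's
maximum could provide alone. A family whose weights are all zero (an L1
model that selects nothing can genuinely do this) is flagged degenerate
and contributes 0 everywhere rather than raising a division error; the
threshold is not rescaled, which makes selection slightly conservative
in that case.

## Pipeline model and assumptions

Input is a merged multi-cohort gene-by-sample log2 intensity matrix
with per-sample class (control/case) and batch labels. Assumptions:
intensities are approximately Gaussian per gene on the log2 scale;
batch effects are per-gene location/scale distortions; classes are
present in every batch used for fitting.

Stage order is fixed: duplicate-probe averaging → log2 (only when the
input is flagged linear-scale) → quantile normalization → batch
adjustment → batch-level split → differential expression on the
training split → model fitting → weight fusion → per-gene ROC →
fraction correlation. Whether to quantile-normalize before or after
batch adjustment is genuinely open; this package normalizes first so
the batch adjuster sees distribution-matched columns, and documents
rather than infers that order.

**Quantile normalization** maps every column onto the mean of the
order statistics; ties receive the mean of the reference values at
their tied (average) ranks, which keeps the map deterministic.

**Batch adjustment** standardizes every batch, per gene, to the grand
mean and the pooled *within-batch* standard deviation
√(Σ_b (n_b − 1)s²_b / (N − B)). Targeting the within-batch pooled
variance (rather than the grand variance, which includes between-batch
spread) makes the operation exactly idempotent — a second application
is the identity to float precision — and matches the generator's
location-scale batch model. This is a deliberate simplification of
empirical-Bayes batch correction (ComBat): no shrinkage across genes,
no covariate design. It removes exactly the structure the generator
plants; on real data with outlier-driven variance estimates, shrinkage
methods are more robust. Genes with zero variance inside a batch get a
location-only shift there.

**The split** assigns whole batches (never individual samples) to
train or test, minimizing |n_train/n_test − 5| over all 2^B partitions
(B ≤ 20) subject to both classes appearing in both splits; ties break
lexicographically on the sorted train-batch tuple, so the result is
deterministic under any seed.

**Differential expression** uses Welch's unequal-variance t by default
(a rank-sum alternative is available); this is a self-contained
substitute for moderated-t approaches whose empirical-Bayes variance
pooling is out of scope — with training splits of ~160 samples the
moderation would change little. Benjamini–Hochberg adjustment is the
standard step-up rule (adj(i) = min_{j ≥ rank(i)} m·p_(j)/j, capped at
1), hand-implemented because the selection contract depends on it, and
cross-checked in tests against an independent reference
implementation. Both selection thresholds are strict: |log2FC| > 1,
FDR < 0.001. Genes constant across both classes get p = 1 by
convention (p = 0 in the measure-zero case of zero variance with
unequal means).

**AUC** uses the Mann–Whitney average-rank identity
(R₁ − n₁(n₁+1)/2)/(n₁n₀), ties counting one half, verified in tests
against exhaustive pair counting. Because candidates may be up- or
down-regulated, orientation is auto-selected so AUC ≥ 0.5 and the
direction (case_higher/case_lower) is reported rather than discarded.
Group comparisons route through a Shapiro–Wilk gate at α = 0.05 per
group (Welch t if neither group rejects normality, rank-sum
otherwise); the gate is an explicit, deterministic choice.

**Immune correlation** is plain Pearson r with the t-transform p-value
(n − 2 df), computed between each candidate gene and each cell-type
fraction column over all samples of the batch-adjusted matrix. No
multiple-testing correction is applied across the gene × cell-type
grid — reported per-pair significance at α = 0.05 is nominal, and this
is deliberately surfaced here and in the output metadata.

## Model-family defaults

| family | key settings (defaults) | importance |
|---|---|---|
| lasso | binomial objective, L1, penalty grid 10⁻⁴…10², 10-fold CV on accuracy | coefficient (signed) |
| svm_linear | linear kernel, cost grid 1…20, 10-fold CV, smallest cost on ties | hyperplane weight (signed) |
| decision_tree | Gini CART, min impurity decrease 10⁻⁵ | summed impurity decrease, primary splits only (unused genes exactly 0) |
| random_forest | up to 500 trees in steps of 50, count at the OOB-error minimum | mean impurity decrease |
| gbm | 200 trees, learning rate 0.001, subsample 0.9, Bernoulli loss | relative influence (gain) |
| neural_net | hidden layers 8-5-3 (configurable), logistic activations, linear output, squared-error loss via L-BFGS, prediction threshold 0.5 | Garson absolute connection-weight products (Olden signed variant behind `signed_importance`) |

All families are fit on per-gene z-scores computed from training
moments only; test data reuses those moments (no leakage). The
penalized and distance-based families need the common scale; trees are
scale-invariant, so applying it uniformly is harmless and keeps one
code path. Hidden-layer sizes and the boosting fold structure are not
externally constrained; the defaults above are explicit configuration
values, not inferences. 10-fold CV is stratified and fold assignment
is seed-deterministic; k is reduced with a warning when a class has
fewer than 10 training samples. Exact bitwise reproducibility under a
fixed seed holds on the same machine for all six families.

## What the generator emulates — and what it does not

`synthetic.default_config` encodes the package's reference study
conditions: 500 genes; six batches sized (40, 44), (36, 40), (5, 4),
(4, 4), (4, 3), (4, 4) (control, case) so the optimal batch-level
split is exactly 160 train / 32 test = 5:1, emulating a merged cohort
of two large and four small arrays; 20 planted genes — 3 strong at
|log2FC| = 3.0 and 17 moderate at |log2FC| = 1.4, mixed signs — so the
expression filter passes ~20 genes of which three dominate; per-gene
baselines N(8, 2²) log2 units (a typical microarray spread; the wide
spread also keeps quantile normalization from compressing planted
effects); measurement noise SD 0.5; per-gene batch shifts SD 0.5 and
log-scale batch noise-scale factors SD 0.1; 10% duplicate probes.
Duplicate probes share the gene's signal with independent noise,
exercising the probe-averaging step. A single global seed is split
hierarchically into one stream per batch plus streams for gene
baselines and duplicate noise, so identical configs reproduce byte-
identical datasets and batch streams are stable under config edits.

Fractions are generated as normalized log-normal latent abundances per
cell type; a linked (gene, cell type, target r) triple blends the
standardized gene expression into that cell type's latent with weight
r. The simplex normalization attenuates the realized correlation below
the target (target 0.9 lands near 0.85 at n = 200) but preserves its
sign — adequate for testing recovery, not a calibrated deconvolution
model.

Not emulated: probe-level artifacts (spatial effects, dye bias),
heavy-tailed or intensity-dependent noise, gene–gene correlation
networks, platform-specific formats, and realistic immune-composition
priors. Passing tests therefore demonstrate correctness of the
machinery and recoverability of location-scale-structured signals, not
performance on real cohort heterogeneity.

## Problem sizes and numerical choices

Test and acceptance workloads use the reference conditions at 500
genes: 25 seeded replicates for planted-signal recovery (top-3 by
overall weight, held-out AUC > 0.85, each required in ≥ 90% of runs),
100 seeded replicates at reduced cohort size for null calibration
(empty DEG table in ≥ 95%), and 200 random instances per oracle check.
Tolerances: 1e-12 for algebraic identities (fusion oracle,
invariances, Pearson against the textbook formula), 1e-9 for
idempotence of normalization/adjustment, and interval assertions for
stochastic rates. Ties: quantile normalization averages reference
values at tied ranks; candidate ordering breaks ties lexicographically
by gene id; the SVM cost grid keeps the smallest cost among equals.
Degenerate inputs: all-zero importance vectors are flagged, not fatal;
constant genes get conventional p-values; a batch with one sample is
an error naming the batch; an empty DEG table stops the pipeline
gracefully before training with an explanatory manifest message.

## Known limitations

- The batch adjuster assumes location-scale batch effects; monotone
  nonlinear distortions are only partially removed by the preceding
  quantile normalization.
- Importances of strongly correlated genes are split arbitrarily
  within tree ensembles; the fusion statistic inherits that
  instability (visible as occasional top-3 misses in the recovery
  runs).
- Garson importance ignores activation nonlinearities and can misrank
  genes in deep, saturated networks; it is used because it is
  non-negative and standard, with Olden's signed variant available.
- The weak-learning-rate boosting configuration (0.001 over 200 trees)
  barely moves predictions from the prior; its *accuracy* is close to
  the majority rate even when its gain-based ranking is informative.
- No confidence intervals are reported for AUCs, and fraction
  correlations are uncorrected for multiple testing.
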