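"""Preprocessing contracts: probe averaging, quantile normalization,
batch adjustment, and the 5:1 batch-level split."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

from dcmprio.preprocess import (
    adjust_batches,
    average_duplicate_probes,
    quantile_normalize,
    split_batches,
)
from dcmprio.synthetic import SynthConfig, generate_dataset


def _ann(labels, batches):
    return pd.DataFrame(
        {"label": labels, "batch": batches, "split": "unassigned"},
        index=[f"S{i}" for i in range(len(labels))],
    )


class TestAverageDuplicateProbes:
    def test_duplicates_are_averaged_per_sample(self):
        matrix = pd.DataFrame(
            [[4.0, 8.0], [6.0, 10.0], [1.0, 2.0]],
            index=["p1", "p2", "p3"], columns=["S0", "S1"],
        )
        probe_map = pd.Series(["G", "G", "H"], index=matrix.index)
        out = average_duplicate_probes(matrix, probe_map)
        assert out.loc["G"].tolist() == [5.0, 9.0]
        assert out.loc["H"].tolist() == [1.0, 2.0]

    def test_no_duplicates_is_identity_up_to_row_order(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.normal(size=(5, 3)),
                              index=["pB", "pA", "pE", "pC", "pD"],
                              columns=list("XYZ"))
        probe_map = pd.Series(["B", "A", "E", "C", "D"], index=matrix.index)
        out = average_duplicate_probes(matrix, probe_map)
        assert list(out.index) == ["A", "B", "C", "D", "E"]
        np.testing.assert_allclose(out.loc["A"], matrix.loc["pA"])

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(5)
        matrix = pd.DataFrame(rng.normal(size=(50, 8)),
                              index=[f"p{i}" for i in range(50)],
                              columns=[f"S{j}" for j in range(8)])
        genes = [f"G{i % 17}" for i in range(50)]
        probe_map = pd.Series(genes, index=matrix.index)
        out = average_duplicate_probes(matrix, probe_map)
        # brute-force oracle: explicit per-gene row means
        for gene in sorted(set(genes)):
            rows = [p for p, g in zip(matrix.index, genes) if g == gene]
            expected = matrix.loc[rows].to_numpy().mean(axis=0)
            np.testing.assert_allclose(out.loc[gene], expected, atol=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            average_duplicate_probes(pd.DataFrame(), pd.Series(dtype=object))


class TestQuantileNormalize:
    def test_hand_computed_two_sample_example(self):
        matrix = pd.DataFrame({"c1": [1.0, 3.0], "c2": [8.0, 2.0]},
                              index=["g1", "g2"])
        out = quantile_normalize(matrix)
        # order statistic means: (1+2)/2 = 1.5, (3+8)/2 = 5.5
        assert out["c1"].tolist() == [1.5, 5.5]
        assert out["c2"].tolist() == [5.5, 1.5]

    def test_identical_columns_unchanged(self):
        col = np.array([4.0, 2.0, 9.0, 7.0])
        matrix = pd.DataFrame({"a": col, "b": col, "c": col})
        np.testing.assert_allclose(quantile_normalize(matrix), matrix)

    def test_all_columns_share_sorted_values_and_means(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(rng.normal(size=(40, 6)) * [1, 2, 3, 1, 5, 1])
        out = quantile_normalize(matrix).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)
        np.testing.assert_allclose(out.mean(axis=0), out[:, 0].mean(), atol=1e-12)

    def test_ties_get_mean_of_tied_rank_references(self):
        matrix = pd.DataFrame({"c1": [1.0, 1.0, 5.0], "c2": [2.0, 4.0, 6.0]})
        out = quantile_normalize(matrix)
        # reference = (1.5, 2.5, 5.5); tied pair takes mean of ranks 1,2
        assert out["c1"].tolist() == [2.0, 2.0, 5.5]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(rng.normal(size=(30, 5)))
        once = quantile_normalize(matrix)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-9)


class TestAdjustBatches:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.normal(size=(10, 6)),
                              columns=[f"S{i}" for i in range(6)])
        ann = _ann(["control"] * 3 + ["case"] * 3, ["B1"] * 6)
        out = adjust_batches(matrix, ann)
        np.testing.assert_allclose(out, matrix, atol=1e-9)

    def test_constant_offset_between_batches_removed(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(20, 4))
        matrix = pd.DataFrame(np.hstack([base, base + 3.0]),
                              columns=[f"S{i}" for i in range(8)])
        ann = _ann(["control", "case"] * 4, ["B1"] * 4 + ["B2"] * 4)
        out = adjust_batches(matrix, ann)
        m1 = out.iloc[:, :4].mean(axis=1)
        m2 = out.iloc[:, 4:].mean(axis=1)
        assert (m1 - m2).abs().max() < 1e-9

    def test_batch_f_statistic_drops_below_null_quantile(self):
        cfg = SynthConfig(n_genes=200, samples_per_batch=((15, 15), (10, 10)),
                          batch_shift_sd=1.0, batch_scale_sd=0.0,
                          noise_sd=0.5, seed=6)
        ds = generate_dataset(cfg)
        ann = ds.annotation
        out = adjust_batches(ds.matrix, ann)
        from scipy.stats import f as f_dist
        crit = f_dist.ppf(0.99, 1, ds.matrix.shape[1] - 2)
        below = 0
        groups = [ann.index[ann["batch"] == b] for b in ("B1", "B2")]
        for g in out.index:
            stat = f_oneway(*[out.loc[g, idx] for idx in groups]).statistic
            below += (not np.isfinite(stat)) or stat < crit
        assert below >= 0.95 * len(out)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        matrix = pd.DataFrame(rng.normal(size=(15, 10)),
                              columns=[f"S{i}" for i in range(10)])
        ann = _ann(["control", "case"] * 5, ["B1"] * 6 + ["B2"] * 4)
        once = adjust_batches(matrix, ann)
        twice = adjust_batches(once, ann)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_zero_variance_gene_gets_location_only_shift(self):
        matrix = pd.DataFrame(
            [[5.0, 5.0, 8.0, 8.0], [1.0, 2.0, 3.0, 4.0]],
            index=["flat", "varying"], columns=[f"S{i}" for i in range(4)],
        )
        ann = _ann(["control", "case"] * 2, ["B1", "B1", "B2", "B2"])
        out = adjust_batches(matrix, ann)
        np.testing.assert_allclose(out.loc["flat"], [6.5] * 4)

    def test_singleton_batch_rejected_by_name(self):
        matrix = pd.DataFrame(np.ones((3, 3)), columns=["S0", "S1", "S2"])
        ann = _ann(["control", "case", "case"], ["B1", "B1", "B2"])
        with pytest.raises(ValueError, match="B2"):
            adjust_batches(matrix, ann)


class TestSplitBatches:
    @staticmethod
    def _cohort(batch_sizes):
        labels, batches = [], []
        for b, (n_ctrl, n_case) in enumerate(batch_sizes):
            labels += ["control"] * n_ctrl + ["case"] * n_case
            batches += [f"B{b + 1}"] * (n_ctrl + n_case)
        return _ann(labels, batches)

    def test_cohort_like_two_large_four_small_puts_large_in_train(self):
        # two large arrays (320 samples) and four small ones (66)
        ann = self._cohort([(76, 86), (76, 82), (8, 12), (6, 10), (7, 9), (6, 8)])
        out = split_batches(ann, ratio=5.0)
        train_batches = set(out.loc[out["split"] == "train", "batch"])
        assert train_batches == {"B1", "B2"}
        assert (out["split"] == "train").sum() == 320
        assert (out["split"] == "test").sum() == 66

    def test_two_equal_batches_split_one_to_one(self):
        ann = self._cohort([(5, 5), (5, 5)])
        out = split_batches(ann, ratio=5.0, seed=0)
        assert set(out["split"]) == {"train", "test"}
        again = split_batches(ann, ratio=5.0, seed=0)
        assert out.equals(again)

    def test_chosen_partition_is_optimal_by_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        sizes = [(int(a), int(b)) for a, b in
                 rng.integers(2, 30, size=(10, 2))]
        ann = self._cohort(sizes)
        out = split_batches(ann, ratio=5.0)
        achieved = abs((out["split"] == "train").sum()
                       / (out["split"] == "test").sum() - 5.0)

        # brute-force oracle over all 2^10 assignments
        batch_ids = sorted(ann["batch"].unique())
        totals = {b: (ann["batch"] == b).sum() for b in batch_ids}
        ctrls = {b: ((ann["batch"] == b) & (ann["label"] == "control")).sum()
                 for b in batch_ids}
        cases = {b: ((ann["batch"] == b) & (ann["label"] == "case")).sum()
                 for b in batch_ids}
        best = np.inf
        for mask in itertools.product([0, 1], repeat=len(batch_ids)):
            train = [b for b, m in zip(batch_ids, mask) if m]
            test = [b for b, m in zip(batch_ids, mask) if not m]
            if not train or not test:
                continue
            if min(sum(ctrls[b] for b in train), sum(cases[b] for b in train),
                   sum(ctrls[b] for b in test), sum(cases[b] for b in test)) == 0:
                continue
            n_train = sum(totals[b] for b in train)
            n_test = sum(totals[b] for b in test)
            best = min(best, abs(n_train / n_test - 5.0))
        assert achieved == pytest.approx(best)

    def test_whole_batches_never_straddle_splits(self, preprocessed):
        _, annotation = preprocessed
        straddling = annotation.groupby("batch")["split"].nunique()
        assert (straddling == 1).all()

    def test_impossible_class_coverage_rejected(self):
        ann = self._cohort([(4, 0), (3, 0)])
        ann.loc[ann["batch"] == "B2", "label"] = "case"
        # B1 all control, B2 all case: no partition covers both classes twice
        with pytest.raises(ValueError):
            split_batches(ann, ratio=5.0)

    def test_sample_order_preserved(self, demo_dataset):
        out = split_batches(demo_dataset.annotation, ratio=5.0)
        assert list(out.index) == list(demo_dataset.annotation.index)
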