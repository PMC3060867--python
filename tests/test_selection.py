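from math import comb

import numpy as np
import pytest

from gradesig.selection import (
    Signature,
    best_subset_size,
    consensus_signature,
    exhaustive_k_search,
    group_signature,
    make_split_plan,
)
from gradesig.svm_rfe import FeatureMatrix

from conftest import separable_blobs, synergistic_pair_fixture


class TestSplitPlan:
    def test_study_sized_defaults(self):
        labels = np.array([1] * 37 + [-1] * 17)  # 54 patients, high vs low grade
        plan = make_split_plan(labels, n_splits=500, n_groups=10, seed=0)
        assert plan.n_splits == 500
        assert len(plan.group(0)) == 50
        for train, test in plan.splits[:20]:
            assert abs(len(train) - len(test)) <= 1
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == 54
            # stratification: both classes on both sides
            assert np.unique(labels[train]).size == 2
            assert np.unique(labels[test]).size == 2

    def test_same_seed_identical_plan(self):
        labels = np.array([1] * 10 + [-1] * 10)
        p1 = make_split_plan(labels, 20, 4, seed=5)
        p2 = make_split_plan(labels, 20, 4, seed=5)
        for (a1, b1), (a2, b2) in zip(p1.splits, p2.splits):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)

    def test_indivisible_groups_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_split_plan(np.array([1, 1, -1, -1]), n_splits=10, n_groups=3)

    def test_tiny_class_rejected(self):
        labels = np.array([1] * 9 + [-1])
        with pytest.raises(ValueError, match="-1"):
            make_split_plan(labels, 10, 2)


def planted_signature_matrix(seed, n_genes=500, n_signal=10, effect=1.2, n=60, noise=0.5):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    X = rng.normal(0, noise, size=(n, n_genes))
    signal = [f"g{j:03d}" for j in range(n_signal)]
    for j in range(n_signal):
        X[:, j] += (y == 1) * effect
    names = [f"g{j:03d}" for j in range(n_genes)]
    return FeatureMatrix(X, y, names), set(signal)


class TestGroupSignature:
    def test_planted_genes_recovered(self):
        # per-split selection size sits above the expected panel size so one
        # RFE miss cannot cost a true gene its vote
        fm, signal = planted_signature_matrix(seed=0)
        plan = make_split_plan(fm.labels, n_splits=50, n_groups=1, seed=0)
        sig = group_signature(fm, plan.group(0), target_size=15,
                              vote_threshold=0.7, prescreen_top=50)
        assert len(set(sig.genes) & signal) >= 8

    def test_zero_threshold_is_union(self):
        fm, _ = planted_signature_matrix(seed=1, n_genes=50)
        plan = make_split_plan(fm.labels, n_splits=4, n_groups=1, seed=1)
        sig = group_signature(fm, plan.group(0), target_size=5, vote_threshold=0.0)
        selected_any = set(sig.genes)
        assert len(selected_any) >= 5  # union over 4 splits
        assert all(sig.vote_fraction[g] > 0 for g in sig.genes)

    def test_threshold_clamped_and_unanimity(self):
        fm, signal = planted_signature_matrix(seed=2)
        plan = make_split_plan(fm.labels, n_splits=6, n_groups=1, seed=2)
        sig = group_signature(fm, plan.group(0), target_size=10,
                              vote_threshold=1.5, prescreen_top=50)
        assert all(f == 1.0 for f in sig.vote_fraction.values())

    def test_empty_signature_warns_not_errors(self, caplog):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 200))  # pure noise: votes scatter
        y = np.array([1] * 20 + [-1] * 20)
        fm = FeatureMatrix(X, y, [f"f{i}" for i in range(200)])
        plan = make_split_plan(y, n_splits=10, n_groups=1, seed=3)
        sig = group_signature(fm, plan.group(0), target_size=3, vote_threshold=1.0)
        assert isinstance(sig.genes, list)  # may be empty; must not raise


class TestConsensus:
    def _sig(self, genes, contrast="c", mode="EFC"):
        return Signature(genes=list(genes), feature_mode=mode, contrast=contrast,
                         vote_fraction={g: 1.0 for g in genes})

    def test_identical_signatures(self):
        sigs = [self._sig(["a", "b", "c"]) for _ in range(10)]
        cons, report = consensus_signature(sigs)
        assert set(cons.genes) == {"a", "b", "c"}
        assert np.all(report["jaccard"] == 1.0)

    def test_strict_majority_excludes_half(self):
        sigs = [self._sig(["a", "x"])] * 5 + [self._sig(["a"])] * 5
        cons, report = consensus_signature(list(sigs))
        assert "a" in cons.genes
        assert "x" not in cons.genes  # 5 of 10 is not > half
        assert report["support"]["x"] == 5

    def test_mismatched_contrasts_rejected(self):
        with pytest.raises(ValueError):
            consensus_signature([self._sig(["a"], "c1"), self._sig(["a"], "c2")])

    def test_consensus_recall_at_least_median_group_recall(self):
        fm, signal = planted_signature_matrix(seed=4)
        plan = make_split_plan(fm.labels, n_splits=40, n_groups=4, seed=4)
        sigs = [
            group_signature(fm, plan.group(g), target_size=10,
                            vote_threshold=0.7, prescreen_top=50)
            for g in range(4)
        ]
        cons, _ = consensus_signature(sigs)
        recalls = [len(set(s.genes) & signal) / len(signal) for s in sigs]
        cons_recall = len(set(cons.genes) & signal) / len(signal)
        assert cons_recall >= np.median(recalls) - 1e-9


class TestBestSubsetSize:
    def test_argmax_on_fixture_table(self):
        table = {10: [0.8, 0.82], 19: [0.9, 0.92], 30: [0.85, 0.85]}
        assert best_subset_size(table) == 19

    def test_tie_goes_to_smaller(self):
        assert best_subset_size({12: [0.9], 10: [0.9]}) == 10


class TestExhaustiveSearch:
    def test_combination_count(self):
        fm = separable_blobs(seed=5, n_features=4)
        res = exhaustive_k_search(fm, fm.feature_names, k=2, cv_folds=2, seed=0)
        assert len(res) == comb(4, 2) == 6

    def test_top_result_dominates_all(self):
        fm, _ = synergistic_pair_fixture(seed=6, n_genes=8)
        res = exhaustive_k_search(fm, fm.feature_names, k=2, cv_folds=5, seed=0)
        assert all(res[0].cv_accuracy >= r.cv_accuracy for r in res)

    def test_planted_pair_found(self):
        fm, pair = synergistic_pair_fixture(seed=7)
        res = exhaustive_k_search(fm, fm.feature_names, k=2, cv_folds=5, seed=0)
        top3 = [r.combo for r in res[:3]]
        assert pair in top3

    def test_perfect_single_gene_ranks_first(self):
        fm = separable_blobs(seed=8, n_features=3)
        rng = np.random.default_rng(8)
        fm.values[:, 1] = rng.normal(size=fm.n_samples)  # degrade the others
        fm.values[:, 2] = rng.normal(size=fm.n_samples)
        res = exhaustive_k_search(fm, fm.feature_names, k=1, cv_folds=5, seed=0)
        assert res[0].combo == ("f0",)
        assert res[0].cv_accuracy == 1.0

    def test_budget_enforced(self):
        fm = separable_blobs(seed=9, n_features=10)
        with pytest.raises(ValueError, match="budget"):
            exhaustive_k_search(fm, fm.feature_names, k=4, budget=10)

    def test_deterministic_ranking(self):
        fm, _ = synergistic_pair_fixture(seed=10, n_genes=10)
        r1 = exhaustive_k_search(fm, fm.feature_names, k=2, cv_folds=5, seed=3)
        r2 = exhaustive_k_search(fm, fm.feature_names, k=2, cv_folds=5, seed=3)
        assert [r.combo for r in r1] == [r.combo for r in r2]
        assert [r.cv_accuracy for r in r1] == [r.cv_accuracy for r in r2]
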