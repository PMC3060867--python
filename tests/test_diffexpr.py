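"""Differential-expression statistics against independent brute-force oracles."""

from itertools import combinations, product
from math import comb

import numpy as np
import pytest
from scipy import stats

from gradesig.diffexpr import (
    call_de_genes,
    core_extended_sets,
    fold_change_count_test,
    grade_independent_genes,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from gradesig.synthetic import SyntheticConfig, generate_cohort


# ---------------------------------------------------------------------------
# Independent enumeration oracles
# ---------------------------------------------------------------------------

def signed_rank_oracle(diffs):
    """Exact two-sided p by enumerating all 2^n sign assignments of the
    magnitudes (tie-free inputs): the null probability of a W+ at least as
    far from its mean as observed."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean) >= abs(w_obs - mean) - 1e-9:
            count += 1
    return w_obs, count / 2**n


def rank_sum_oracle(a, b):
    """Exact two-sided p by enumerating all C(n_a+n_b, n_a) rank splits."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = a.size
    r_obs = ranks[:n_a].sum()
    mean = n_a * (pooled.size + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(pooled.size), n_a):
        r = ranks[list(idx)].sum()
        total += 1
        if abs(r - mean) >= abs(r_obs - mean) - 1e-9:
            count += 1
    return count / total


class TestSignedRankAgainstOracle:
    def test_all_positive_n5(self):
        w, p = wilcoxon_signed_rank([1.1, 0.9, 1.3, 1.2, 1.0])
        assert w == 15.0
        assert p == pytest.approx(0.0625)

    def test_balanced_pair(self):
        _, p = wilcoxon_signed_rank([-1.0, 1.0])
        assert p == 1.0

    def test_mixed_signs_matches_enumeration(self):
        diffs = [2, -0.1, 1.5, 1.8, -0.2, 1.9, 2.2, 1.4]
        w, p = wilcoxon_signed_rank(diffs)
        w_oracle, p_oracle = signed_rank_oracle(diffs)
        assert w == w_oracle
        assert p == pytest.approx(p_oracle, abs=1e-12)

    @pytest.mark.parametrize("n", range(3, 11))
    def test_random_inputs_all_n_up_to_10(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            diffs = rng.normal(0.3, 1.0, size=n)
            _, p = wilcoxon_signed_rank(diffs)
            _, p_oracle = signed_rank_oracle(diffs)
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_all_zero_is_degenerate(self):
        w, p = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert p == 1.0

    def test_zeros_dropped_before_ranking(self):
        d = [1.2, -0.7, 0.0, 0.4]
        assert wilcoxon_signed_rank(d) == wilcoxon_signed_rank([1.2, -0.7, 0.4])


class TestRankSumAgainstOracle:
    def test_extreme_separation(self):
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_groups(self):
        # tie-heavy identical groups -> no evidence of difference
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_gaussian_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=8)
        b = rng.normal(0.5, 1, size=8)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(rank_sum_oracle(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestFoldChangeCountTest:
    def test_all_ten_pairs_exceed(self):
        k, p = fold_change_count_test([1.2] * 10, fc_threshold=2, direction="up")
        assert k == 10
        assert p == pytest.approx(1 / 1024)

    def test_seven_of_ten(self):
        fc = [1.5] * 7 + [0.0] * 3
        k, p = fold_change_count_test(fc, direction="up")
        assert k == 7
        assert p == pytest.approx(176 / 1024)

    def test_zero_count_upper_tail_is_one(self):
        k, p = fold_change_count_test([0.0] * 10, direction="up")
        assert (k, p) == (0, 1.0)

    def test_down_direction_counts_negative_fc(self):
        k, _ = fold_change_count_test([-1.5, -1.0, 0.5], direction="down")
        assert k == 2

    def test_p_monotone_nonincreasing_in_k(self):
        n = 12
        ps = []
        for k in range(n + 1):
            fc = [1.5] * k + [0.0] * (n - k)
            ps.append(fold_change_count_test(fc, direction="up")[1])
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_threshold_is_log2_of_ratio(self):
        # 2-fold on log2 scale = 1.0; exactly 1.0 counts
        k, _ = fold_change_count_test([1.0, 0.99], fc_threshold=2, direction="up")
        assert k == 1


class TestCallDEGenes:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = SyntheticConfig(
            n_genes=1000, n_de_genes=25, de_effect=1.5,
            patients_per_grade={"WD": 5, "MD": 5, "PD": 5, "UD": 5},
            noise_sd=0.3, seed=21,
        )
        cohort, truth = generate_cohort(cfg)
        return call_de_genes(cohort), truth

    def test_planted_genes_called_by_both_strategies(self, planted):
        results, truth = planted
        by_gene = {r.gene: r for r in results}
        both = sum(
            by_gene[g].called_wilcoxon and by_gene[g].called_count
            for g in truth.de_genes
        )
        assert both >= 0.9 * len(truth.de_genes)

    def test_null_call_rate_controlled(self, planted):
        results, truth = planted
        null_w = [r.called_wilcoxon for r in results if r.gene in truth.null_genes]
        # conjunction rule (2-fold AND p<0.05) is far more conservative than alpha
        assert np.mean(null_w) <= 0.05

    def test_direction_matches_planted_sign(self, planted):
        results, truth = planted
        by_gene = {r.gene: r for r in results}
        for g, eff in truth.de_genes.items():
            assert by_gene[g].direction == ("up" if eff > 0 else "down")

    def test_small_fc_not_called_despite_tiny_p(self):
        # half-fold shift, tiny noise: p is tiny but the 2-fold rule fails
        rng = np.random.default_rng(5)
        from conftest import make_cohort

        n = 20
        ref = rng.uniform(6, 7, size=n)
        vals = np.empty((1, 2 * n))
        vals[0, 0::2] = ref + 0.5
        vals[0, 1::2] = ref
        results = call_de_genes(make_cohort(vals))
        r = results[0]
        assert r.p_wilcoxon_paired < 1e-4
        assert not r.called_wilcoxon
        assert abs(r.mean_log2fc - 0.5) < 1e-9


class TestCoreExtendedSets:
    def test_set_logic(self, ):
        from gradesig.diffexpr import DEResult

        def res(gene, w, c):
            return DEResult(gene, 1.5, 0.01, 0.01, 5, 0.01, w, c, "up")

        results = [res("a", True, False), res("b", True, True), res("c", False, False)]
        s = core_extended_sets(results, group="PD")
        assert s.extended_set == {"a", "b"}
        assert s.core_set == {"b"}
        assert len(s.core_set) <= len(s.extended_set)


class TestGradeIndependentGenes:
    def test_direction_consistency_required(self):
        from gradesig.diffexpr import DESetSummary

        def summ(group, genes_dirs):
            return DESetSummary(
                group=group,
                extended_set=set(genes_dirs),
                core_set=set(),
                n_wilcoxon=0,
                n_count=0,
                directions=dict(genes_dirs),
            )

        groups = [summ(f"g{i}", {"x": "up", "y": "up"}) for i in range(7)]
        groups.append(summ("g7", {"x": "up", "y": "down"}))
        out = grade_independent_genes(groups)
        assert out == {"x"}

    def test_planted_global_de_gene_recovered(self):
        cfg = SyntheticConfig(
            n_genes=300, n_de_genes=5, de_effect=2.0,
            patients_per_grade={"WD": 6, "MD": 6, "PD": 6, "UD": 6},
            patients_per_stage={"I": 6, "II": 6, "III": 6, "IV": 6},
            noise_sd=0.3, seed=31,
        )
        cohort, truth = generate_cohort(cfg)
        summaries = []
        for axis, levels in (("grade", ["WD", "MD", "PD", "UD"]), ("stage", ["I", "II", "III", "IV"])):
            for lev in levels:
                pats = sorted({s.patient_id for s in cohort.samples if getattr(s, axis) == lev})
                results = call_de_genes(cohort, patients=pats)
                summaries.append(core_extended_sets(results, group=f"{axis}:{lev}"))
        recovered = grade_independent_genes(summaries)
        assert len(recovered & set(truth.de_genes)) >= 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            grade_independent_genes([])
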