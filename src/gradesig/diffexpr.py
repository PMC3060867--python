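"""Differential-expression calling for paired tumor/reference cohorts.

Two complementary strategies are implemented per gene:

* Paired strategy: Wilcoxon signed-rank test on per-patient log2 fold
  changes, combined with a gene-level fold-change requirement
  (|mean log2fc| >= log2(fc_threshold), p < alpha).
* Count strategy: K_exp, the number of patient pairs whose fold change
  exceeds the threshold in a given direction, tested against the upper
  tail of Binomial(n_pairs, null_prob). The default sign-null
  (null_prob = 0.5) is conservative for a 2-fold event under any
  symmetric per-pair null.

An unpaired rank-sum test (cancer vs reference pooled) is reported
alongside. P-values are unadjusted by default; a Benjamini-Hochberg
flag is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import ExpressionCohort, PairedFoldChange, compute_paired_fold_changes

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 10


def wilcoxon_signed_rank(diffs) -> tuple[float, float]:
    """Two-sided signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention). The null
    distribution is exact (enumeration over sign assignments) for n <= 25
    without tied magnitudes, and a tie-corrected normal approximation
    otherwise. All-zero input is degenerate and returns (0, 1.0).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= EXACT_SIGNED_RANK_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    # report W+ (sum of positive ranks); scipy's two-sided statistic is min(W+, W-)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, float(res.pvalue)


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Mann-Whitney/rank-sum p-value; exact for small tie-free
    samples, tie-corrected normal approximation otherwise."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= EXACT_RANK_SUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def fold_change_count_test(
    fold_changes,
    fc_threshold: float = 2.0,
    direction: str = "up",
    null_prob: float = 0.5,
) -> tuple[int, float]:
    """K_exp count test: how many pairs exceed the fold threshold.

    Returns (k_exp, p) where p is the exact binomial upper tail
    P(X >= k_exp), X ~ Binomial(n_pairs, null_prob).
    """
    fc = np.asarray(fold_changes, dtype=float)
    if fc.size == 0:
        raise ValueError("fold_changes must be nonempty")
    if not 0.0 < null_prob < 1.0:
        raise ValueError("null_prob must be in (0, 1)")
    cut = math.log2(fc_threshold)
    if direction == "up":
        k_exp = int(np.sum(fc >= cut))
    elif direction == "down":
        k_exp = int(np.sum(fc <= -cut))
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    p = float(stats.binom.sf(k_exp - 1, fc.size, null_prob))
    return k_exp, min(p, 1.0)


@dataclass
class DEResult:
    gene: str
    mean_log2fc: float
    p_wilcoxon_paired: float
    p_unpaired: float
    k_exp: int
    p_count: float
    called_wilcoxon: bool
    called_count: bool
    direction: str  # "up" | "down"
    p_wilcoxon_adj: float | None = None
    p_count_adj: float | None = None


@dataclass
class DESetSummary:
    group: str
    extended_set: set
    core_set: set
    n_wilcoxon: int
    n_count: int
    directions: dict  # gene -> "up"/"down" among called genes

    def __post_init__(self) -> None:
        if not self.core_set <= self.extended_set:
            raise ValueError("core set must be a subset of the extended set")


def call_de_genes(
    cohort: ExpressionCohort,
    patients: "list[str] | None" = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    null_prob: float = 0.5,
    adjust: bool = False,
) -> list[DEResult]:
    """Per-gene DE calls on the (optionally patient-subset) cohort.

    The paired strategy calls a gene when |mean log2fc| >= log2(fc_threshold)
    and the signed-rank p < alpha. The count strategy runs both one-sided
    K_exp tests and calls the gene on its smaller-p side when that p < alpha.
    ``direction`` is the sign of the mean fold change.
    """
    pairs = compute_paired_fold_changes(cohort)
    if patients is not None:
        keep = [i for i, p in enumerate(pairs.patients) if p in set(patients)]
        if len(keep) < 2:
            raise ValueError(f"need >= 2 complete pairs, got {len(keep)}")
        fc = pairs.log2fc[:, keep]
        kept_patients = {pairs.patients[i] for i in keep}
    else:
        if len(pairs.patients) < 2:
            raise ValueError("need >= 2 complete pairs")
        fc = pairs.log2fc
        kept_patients = set(pairs.patients)

    # unpaired test pools cancer vs reference samples of the kept patients
    sample_keep = np.array(
        [s.patient_id in kept_patients for s in cohort.samples], dtype=bool
    )
    cancer_cols = cohort.tissue_mask("cancer") & sample_keep
    ref_cols = cohort.tissue_mask("reference") & sample_keep
    cut = math.log2(fc_threshold)

    results: list[DEResult] = []
    for i, gene in enumerate(cohort.genes):
        d = fc[i]
        mean_fc = float(d.mean())
        _, p_paired = wilcoxon_signed_rank(d)
        p_unpaired = wilcoxon_rank_sum(cohort.values[i, cancer_cols], cohort.values[i, ref_cols])
        k_up, p_up = fold_change_count_test(d, fc_threshold, "up", null_prob)
        k_dn, p_dn = fold_change_count_test(d, fc_threshold, "down", null_prob)
        if p_up <= p_dn:
            k_exp, p_count = k_up, p_up
        else:
            k_exp, p_count = k_dn, p_dn
        results.append(
            DEResult(
                gene=gene,
                mean_log2fc=mean_fc,
                p_wilcoxon_paired=p_paired,
                p_unpaired=p_unpaired,
                k_exp=k_exp,
                p_count=p_count,
                called_wilcoxon=bool(abs(mean_fc) >= cut and p_paired < alpha),
                called_count=bool(p_count < alpha),
                direction="up" if mean_fc >= 0 else "down",
            )
        )
    if adjust:
        from statsmodels.stats.multitest import multipletests

        for attr, adj_attr in (
            ("p_wilcoxon_paired", "p_wilcoxon_adj"),
            ("p_count", "p_count_adj"),
        ):
            adj = multipletests([getattr(r, attr) for r in results], method="fdr_bh")[1]
            for r, q in zip(results, adj):
                setattr(r, adj_attr, float(q))
    return results


def core_extended_sets(results: list[DEResult], group: str) -> DESetSummary:
    """Core = called by both strategies; extended = called by at least one."""
    wilc = {r.gene for r in results if r.called_wilcoxon}
    count = {r.gene for r in results if r.called_count}
    directions = {r.gene: r.direction for r in results if r.called_wilcoxon or r.called_count}
    return DESetSummary(
        group=group,
        extended_set=wilc | count,
        core_set=wilc & count,
        n_wilcoxon=len(wilc),
        n_count=len(count),
        directions=directions,
    )


def grade_independent_genes(
    summaries: list[DESetSummary], use: str = "extended"
) -> set:
    """Genes called in every group with a consistent direction.

    ``use`` selects whether the per-group extended or core set defines
    "called". With summaries over all grades and all stages this yields the
    grade/stage-independent DE genes.
    """
    if not summaries:
        raise ValueError("need at least one group summary")
    sets = [
        (s.extended_set if use == "extended" else s.core_set) for s in summaries
    ]
    common = set.intersection(*sets)
    out = set()
    for gene in common:
        dirs = {s.directions.get(gene) for s in summaries}
        if len(dirs) == 1:
            out.add(gene)
    return out


def de_results_frame(results: list[DEResult]):
    import pandas as pd

    return pd.DataFrame([vars(r) for r in results]).set_index("gene")
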