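"""Ensemble signature selection by resampled SVM-RFE with majority voting,
and the exhaustive small-panel (k-gene) combination search.

The resampling scheme: the cohort is split into equal training/test halves
many times (default 500, stratified by class so both classes appear in
every half); the splits are divided into groups (default 10 groups of 50).
Within a group, SVM-RFE selects a gene subset on each split's training
half, a gene enters the group's signature when it is selected in at least a
vote-threshold fraction (default 70%) of the group's training sets, and the
10 group signatures are compared for consistency and merged into a
strict-majority consensus. Test halves are never touched during selection;
they only score candidate subset sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .evaluation import cross_validate
from .svm_rfe import FeatureMatrix, rfe_rank, rfe_select, train_linear_svm

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    splits: list  # (train index array, test index array)
    n_splits: int
    n_groups: int
    seed: int

    def group(self, g: int) -> list:
        per = self.n_splits // self.n_groups
        return self.splits[g * per : (g + 1) * per]


@dataclass
class Signature:
    genes: list
    feature_mode: str  # "REL" | "EFC"
    contrast: str
    vote_fraction: dict = field(default_factory=dict)  # gene -> fraction
    seed: int | None = None
    params: dict = field(default_factory=dict)


@dataclass
class ComboResult:
    combo: tuple
    cv_accuracy: float
    cv_sensitivity: float
    cv_specificity: float


def make_split_plan(
    labels,
    n_splits: int = 500,
    n_groups: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Seeded stratified half-splits, grouped.

    Each split puts half of every class (odd counts alternate the extra
    sample) into training and the rest into test; training and test are
    disjoint and cover all samples.
    """
    y = np.asarray(labels)
    if y.size < 4:
        raise ValueError("need at least 4 samples to half-split")
    if n_splits % n_groups != 0:
        raise ValueError(f"n_splits ({n_splits}) must be divisible by n_groups ({n_groups})")
    for cls in np.unique(y):
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples; cannot stratify")
    rng = np.random.default_rng(seed)
    class_idx = [np.flatnonzero(y == cls) for cls in np.unique(y)]
    splits = []
    for s in range(n_splits):
        train_parts, test_parts = [], []
        for ci, idx in enumerate(class_idx):
            perm = rng.permutation(idx)
            half = idx.size // 2
            # odd classes alternate the extra sample, staggered by class so
            # the two halves stay within one sample of each other overall
            if idx.size % 2 == 1 and (s + ci) % 2 == 1:
                half += 1
            train_parts.append(perm[:half])
            test_parts.append(perm[half:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts))
        splits.append((train, test))
    return SplitPlan(splits=splits, n_splits=n_splits, n_groups=n_groups, seed=seed)


def _prescreen(data: FeatureMatrix, train: np.ndarray, top: int) -> np.ndarray:
    """Top features by rank-sum p between classes, computed on the training
    half only (test halves stay unseen during selection)."""
    X = data.values[train]
    y = data.labels[train]
    classes = np.unique(y)
    a = X[y == classes[0]]
    b = X[y == classes[1]]
    p = stats.mannwhitneyu(a, b, alternative="two-sided", axis=0).pvalue
    order = np.argsort(p, kind="stable")
    return np.sort(order[:top])


def group_signature(
    data: FeatureMatrix,
    splits: list,
    target_size: int,
    vote_threshold: float = 0.7,
    C: float = 1.0,
    prescreen_top: int | None = None,
    contrast: str = "",
    feature_mode: str = "EFC",
) -> Signature:
    """Majority-voting signature from one group of train/test splits.

    RFE runs on each split's training half (optionally on a per-split
    rank-sum prescreened candidate set); a gene passes when its vote
    fraction reaches the threshold. Genes are ordered by descending vote
    fraction, then by mean RFE rank, then symbol.
    """
    if not splits:
        raise ValueError("group must contain at least one split")
    vote_threshold = min(max(vote_threshold, 0.0), 1.0)
    votes: dict[str, int] = {}
    rank_sum: dict[str, float] = {}
    for train, _test in splits:
        sub = data.subset_samples(train)
        if prescreen_top is not None and prescreen_top < data.n_features:
            keep = _prescreen(data, train, prescreen_top)
            sub = sub.subset_features(keep)
        selected = rfe_select(sub, min(target_size, sub.n_features), C=C)
        for rank, gene in enumerate(selected, start=1):
            votes[gene] = votes.get(gene, 0) + 1
            rank_sum[gene] = rank_sum.get(gene, 0.0) + rank
    n = len(splits)
    fractions = {g: v / n for g, v in votes.items()}
    passing = [g for g, f in fractions.items() if f >= vote_threshold or vote_threshold == 0.0]
    if not passing:
        logger.warning("no gene reached vote threshold %.2f; empty signature", vote_threshold)
    passing.sort(key=lambda g: (-fractions[g], rank_sum[g] / votes[g], g))
    return Signature(
        genes=passing,
        feature_mode=feature_mode,
        contrast=contrast,
        vote_fraction={g: fractions[g] for g in passing},
        params={
            "target_size": target_size,
            "vote_threshold": vote_threshold,
            "C": C,
            "prescreen_top": prescreen_top,
            "n_splits": n,
        },
    )


def consensus_signature(
    group_signatures: list,
) -> tuple[Signature, dict]:
    """Merge group signatures by strict majority (> half of the groups).

    Returns the consensus plus a consistency report: pairwise Jaccard
    similarity matrix and per-gene support counts.
    """
    if len(group_signatures) < 2:
        raise ValueError("need at least 2 group signatures")
    contrasts = {s.contrast for s in group_signatures}
    modes = {s.feature_mode for s in group_signatures}
    if len(contrasts) > 1 or len(modes) > 1:
        raise ValueError(f"mismatched contrasts {contrasts} or feature modes {modes}")
    g = len(group_signatures)
    sets = [set(s.genes) for s in group_signatures]
    support: dict[str, int] = {}
    for s in sets:
        for gene in s:
            support[gene] = support.get(gene, 0) + 1
    consensus_genes = sorted(
        (gene for gene, c in support.items() if c > g / 2),
        key=lambda gene: (-support[gene], gene),
    )
    jaccard = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            union = sets[i] | sets[j]
            jac = len(sets[i] & sets[j]) / len(union) if union else 1.0
            jaccard[i, j] = jaccard[j, i] = jac
    mean_fraction = {
        gene: float(
            np.mean([s.vote_fraction.get(gene, 0.0) for s in group_signatures])
        )
        for gene in consensus_genes
    }
    sig = Signature(
        genes=consensus_genes,
        feature_mode=group_signatures[0].feature_mode,
        contrast=group_signatures[0].contrast,
        vote_fraction=mean_fraction,
        params={"rule": "strict-majority", "n_groups": g},
    )
    report = {"jaccard": jaccard, "support": support}
    return sig, report


def best_subset_size(accuracy_by_size: dict) -> int:
    """Argmax of mean test-half accuracy over candidate subset sizes; ties
    go to the smaller subset."""
    if not accuracy_by_size:
        raise ValueError("empty accuracy table")
    means = {k: float(np.mean(v)) for k, v in accuracy_by_size.items()}
    best = max(means.values())
    return min(k for k, m in means.items() if m >= best - 1e-12)


def best_rfe_classifier(
    data: FeatureMatrix,
    splits: list,
    sizes: list,
    C: float = 1.0,
    prescreen_top: int | None = None,
):
    """Score candidate subset sizes on a group's test halves and refit.

    For each split: RFE on the training half ranks the (prescreened)
    features; for each candidate size, a linear SVM on the top-ranked
    features is scored on the test half. The size with the best mean
    test accuracy (ties -> smaller) is refit on all samples.
    Returns (chosen size, refit model, accuracy table).
    """
    table: dict[int, list] = {s: [] for s in sizes}
    for train, test in splits:
        sub = data.subset_samples(train)
        if prescreen_top is not None and prescreen_top < data.n_features:
            keep = _prescreen(data, train, prescreen_top)
            sub = sub.subset_features(keep)
        trace = rfe_rank(sub, C=C)
        for size in sizes:
            genes = trace.final_ranking[: min(size, len(trace.final_ranking))]
            idx = [data.feature_names.index(g) for g in genes]
            model = train_linear_svm(
                data.subset_samples(train).subset_features(idx), C=C, standardize=True
            )
            pred = model.predict(data.values[np.ix_(test, idx)])
            table[size].append(float((pred == data.labels[test]).mean()))
    size = best_subset_size(table)
    # refit on all data with a final RFE ranking over everything
    full = data
    if prescreen_top is not None and prescreen_top < data.n_features:
        keep = _prescreen(data, np.arange(data.n_samples), prescreen_top)
        full = data.subset_features(keep)
    ranking = rfe_rank(full, C=C).final_ranking[:size]
    idx = [data.feature_names.index(g) for g in ranking]
    model = train_linear_svm(data.subset_features(idx), C=C, standardize=True)
    return size, model, table


def exhaustive_k_search(
    data: FeatureMatrix,
    candidates: list,
    k: int,
    cv_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    budget: int = 10**6,
) -> list:
    """Evaluate every k-gene combination of the candidates by seeded
    stratified cross-validation with a linear SVM.

    Output is exhaustive — exactly C(len(candidates), k) results — sorted
    by cv_accuracy descending, ties by lexicographic gene order.
    """
    if not 1 <= k <= len(candidates):
        raise ValueError(f"k must be in 1..{len(candidates)}")
    n_combos = comb(len(candidates), k)
    if n_combos > budget:
        raise ValueError(
            f"{n_combos} combinations exceed the budget of {budget}; "
            "shrink the candidate list or raise the budget"
        )
    idx = {g: data.feature_names.index(g) for g in candidates}
    results = []
    for combo in combinations(sorted(candidates), k):
        sub = data.subset_features([idx[g] for g in combo])
        rep = cross_validate(sub, folds=cv_folds, seed=seed, C=C)
        results.append(
            ComboResult(
                combo=combo,
                cv_accuracy=rep.overall_accuracy,
                cv_sensitivity=rep.sensitivity,
                cv_specificity=rep.specificity,
            )
        )
    results.sort(key=lambda r: (-r.cv_accuracy, r.combo))
    return results
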