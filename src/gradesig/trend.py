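"""Ordinal trend screening: genes whose per-grade (or per-stage) average
expression changes monotonically with the ordinal level.

The screen follows the per-level-means construction: for each gene, average
expression (REL mode: cancer samples; EFC mode: per-pair log2 fold changes)
within each ordinal level, then correlate the m-point profile with the level
codes 1..m by Spearman rank correlation. The p-value is exact — the observed
one-sided tail over all m! equally likely orderings of the profile — so with
four grades a strictly monotone profile has p = 1/24 < 0.05 and the joint
criterion |CC| = 1, p < alpha is attainable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats

from .datamodel import GRADES, STAGES, ExpressionCohort, compute_paired_fold_changes

logger = logging.getLogger(__name__)

MAX_EXACT_LEVELS = 7
MIN_SAMPLES_WARN = 3


@dataclass
class TrendResult:
    gene: str
    group_means: tuple
    cc: float
    p: float
    perfect: bool


def group_means(
    cohort: ExpressionCohort, axis: str = "grade", feature: str = "EFC"
) -> tuple[list[str], np.ndarray, list[str]]:
    """Per-gene mean profiles over ordinal levels.

    Returns (levels_used, profiles, genes) where profiles is genes x levels.
    REL averages cancer-sample expression per level; EFC averages per-pair
    log2 fold changes per level. Levels with zero samples are dropped with a
    warning, shortening every profile.
    """
    if axis not in ("grade", "stage"):
        raise ValueError("axis must be 'grade' or 'stage'")
    levels = GRADES if axis == "grade" else STAGES
    if feature == "REL":
        cancer = cohort.tissue_mask("cancer")
        labels = np.array(
            [getattr(s, axis) for s in cohort.samples], dtype=object
        )
        cols = {
            lev: np.flatnonzero(cancer & (labels == lev)) for lev in levels
        }
        matrix = cohort.values
    elif feature == "EFC":
        pairs = compute_paired_fold_changes(cohort)
        lab = {p: cohort.patient_label(p, axis) for p in pairs.patients}
        cols = {
            lev: np.array([j for j, p in enumerate(pairs.patients) if lab[p] == lev], dtype=int)
            for lev in levels
        }
        matrix = pairs.log2fc
    else:
        raise ValueError("feature must be 'REL' or 'EFC'")

    used = [lev for lev in levels if cols[lev].size > 0]
    for lev in levels:
        if cols[lev].size == 0:
            logger.warning("%s level %s has no samples; dropped from trend profiles", axis, lev)
        elif cols[lev].size < MIN_SAMPLES_WARN:
            logger.warning(
                "%s level %s has only %d samples; its mean is noisy", axis, lev, cols[lev].size
            )
    profiles = np.column_stack([matrix[:, cols[lev]].mean(axis=1) for lev in used])
    return used, profiles, list(cohort.genes)


def spearman_trend(profile, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Spearman CC of an ordered mean profile against codes 1..m, with the
    exact one-sided permutation p-value over all m! orderings.

    Ties are handled with midranks; ``perfect`` additionally requires the
    profile to be strictly monotone, so a tied |cc| = 1 cannot occur.
    """
    x = np.asarray(profile, dtype=float)
    m = x.size
    if m < 3:
        raise ValueError(f"profile must have >= 3 levels, got {m}")
    codes = np.arange(1, m + 1)
    if np.unique(x).size == 1:
        return 0.0, 1.0, False
    cc = float(stats.spearmanr(x, codes).statistic)
    if m > MAX_EXACT_LEVELS:
        p = float(stats.spearmanr(x, codes).pvalue)
        strict = bool(np.all(np.diff(x) > 0) or np.all(np.diff(x) < 0))
        return cc, p, bool(abs(cc) == 1.0 and p < alpha and strict)
    # Exact one-sided tail in the direction of the observed cc: the fraction
    # of the m! orderings of the profile with cc at least as extreme.
    sign = 1.0 if cc >= 0 else -1.0
    count = 0
    for perm in permutations(x):
        c = float(stats.spearmanr(perm, codes).statistic)
        if sign * c >= sign * cc - 1e-12:
            count += 1
    p = count / factorial(m)
    strict = bool(np.all(np.diff(x) > 0) or np.all(np.diff(x) < 0))
    perfect = bool(abs(cc) == 1.0 and p < alpha and strict)
    return cc, p, perfect


def find_trend_genes(
    cohort: ExpressionCohort,
    axis: str = "grade",
    feature: str = "EFC",
    alpha: float = 0.05,
    perfect_only: bool = True,
) -> list[TrendResult]:
    """Screen all genes; return those with |cc| = 1 and p < alpha (or all
    results if perfect_only is False), sorted by gene symbol."""
    used, profiles, genes = group_means(cohort, axis, feature)
    if len(used) < 3:
        raise ValueError(
            f"only {len(used)} populated {axis} levels; need >= 3 for a trend screen"
        )
    # Monotone profiles all share the same exact p (1/m! one-sided); compute
    # the permutation tail once per distinct rank pattern for speed.
    cache: dict[tuple, tuple[float, float, bool]] = {}
    out: list[TrendResult] = []
    for i, gene in enumerate(genes):
        prof = profiles[i]
        key = tuple(stats.rankdata(prof))  # midranks determine cc, p and strictness
        if key in cache:
            cc, p, perfect = cache[key]
        else:
            cc, p, perfect = spearman_trend(prof, alpha)
            cache[key] = (cc, p, perfect)
        if perfect or not perfect_only:
            out.append(TrendResult(gene, tuple(float(v) for v in prof), cc, p, perfect))
    out.sort(key=lambda r: r.gene)
    return out
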