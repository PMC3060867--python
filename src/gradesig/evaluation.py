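"""ROC/AUC, cutoff selection and cross-validated accuracy reporting.

AUC is the Mann-Whitney probability that a random positive outscores a
random negative (ties count one half); the companion p-value is a two-sided
rank-sum test between the two score distributions. Single-score cutoffs are
placed at midpoints between adjacent distinct observed values and chosen to
maximize Youden's J = sensitivity + specificity - 1, scanning both
orientations so markers that run low in the positive class are handled.
Cross-validation is stratified, seeded, and pools held-out predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .svm_rfe import FeatureMatrix, train_linear_svm

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    auc: float | None = None
    auc_p: float | None = None
    roc_points: list = field(default_factory=list)
    cutoff: float | None = None
    cutoff_orientation: str = ">="  # positives score high (">="), or low ("<=")
    sensitivity: float | None = None
    specificity: float | None = None
    overall_accuracy: float | None = None
    confusion: dict = field(default_factory=dict)  # (true, predicted) -> count
    n_samples: int = 0
    folds: int | None = None
    degenerate: bool = False


def auc(scores, labels) -> tuple[float, float]:
    """(AUC, two-sided rank-sum p) for binary labels; positive = larger label."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    pos = s[y == classes[1]]
    neg = s[y == classes[0]]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    value = float(u.statistic) / (pos.size * neg.size)
    return value, float(u.pvalue)


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """(1 - specificity, sensitivity) swept over descending thresholds,
    from (0,0) to (1,1)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    pos_label = classes[1]
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order] == pos_label
    n_pos = int(y_sorted.sum())
    n_neg = y_sorted.size - n_pos
    pts = [(0.0, 0.0)]
    tp = fp = 0
    s_sorted = s[order]
    i = 0
    while i < y_sorted.size:
        j = i
        while j < y_sorted.size and s_sorted[j] == s_sorted[i]:
            tp += bool(y_sorted[j])
            fp += not y_sorted[j]
            j += 1
        pts.append((fp / n_neg if n_neg else 0.0, tp / n_pos if n_pos else 0.0))
        i = j
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def best_cutoff(scores, labels) -> tuple[float | None, float, float, str, bool]:
    """Youden-optimal midpoint cutoff.

    Returns (cutoff, sensitivity, specificity, orientation, degenerate).
    orientation ">=" means samples at or above the cutoff are called
    positive; "<=" the reverse (chosen when positives score low). Constant
    scores are degenerate: no cutoff, the all-positive rule is reported.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    pos = y == classes[1]
    distinct = np.unique(s)
    if distinct.size == 1:
        sens = 1.0
        spec = 0.0
        return None, sens, spec, ">=", True
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    pos_sorted = np.sort(s[pos])
    neg_sorted = np.sort(s[~pos])
    n_pos, n_neg = pos_sorted.size, neg_sorted.size
    # orientation ">=": call positive at or above the cutoff
    sens_ge = (n_pos - np.searchsorted(pos_sorted, mids, side="left")) / n_pos
    spec_ge = np.searchsorted(neg_sorted, mids, side="left") / n_neg
    # orientation "<=": positives score low
    sens_le = np.searchsorted(pos_sorted, mids, side="right") / n_pos
    spec_le = (n_neg - np.searchsorted(neg_sorted, mids, side="right")) / n_neg
    # interleave so ties keep the first candidate (lowest cutoff, ">=" first)
    J = np.empty(2 * mids.size)
    J[0::2] = sens_ge + spec_ge - 1.0
    J[1::2] = sens_le + spec_le - 1.0
    k = int(np.argmax(J))
    i = k // 2
    if k % 2 == 0:
        return float(mids[i]), float(sens_ge[i]), float(spec_ge[i]), ">=", False
    return float(mids[i]), float(sens_le[i]), float(spec_le[i]), "<=", False


def evaluate_single_gene(scores, labels, alpha: float = 0.05) -> EvaluationReport:
    """Single-marker report: AUC with rank-sum p, ROC, Youden cutoff."""
    a, p = auc(scores, labels)
    cut, sens, spec, orient, degenerate = best_cutoff(scores, labels)
    y = np.asarray(labels)
    classes = np.unique(y)
    return EvaluationReport(
        auc=a,
        auc_p=p,
        roc_points=roc_points(scores, labels),
        cutoff=cut,
        cutoff_orientation=orient,
        sensitivity=sens,
        specificity=spec,
        overall_accuracy=None,
        n_samples=int(y.size),
        degenerate=degenerate,
    )


def _stratified_folds(labels: np.ndarray, folds: int, seed: int):
    _, counts = np.unique(labels, return_counts=True)
    min_class = int(counts.min())
    if min_class < 2:
        raise ValueError("every class needs >= 2 samples for cross-validation")
    if min_class < folds:
        logger.warning("smallest class has %d samples; reducing folds %d -> %d",
                       min_class, folds, min_class)
        folds = min_class
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return folds, skf.split(np.zeros(labels.size), labels)


def cross_validate(
    data: FeatureMatrix,
    signature: "list[str] | None" = None,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> EvaluationReport:
    """Stratified k-fold CV of a linear SVM on the signature's features.

    Binary labels; standardization is learned inside each training fold.
    Pooled held-out predictions give accuracy / sensitivity / specificity
    (sensitivity is w.r.t. the larger class label, the contrast's target),
    and pooled decision values give the cross-validated AUC.
    """
    if signature is not None:
        idx = [data.feature_names.index(g) for g in signature]
        data = data.subset_features(idx)
    y = data.labels
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("cross_validate is binary; use multigroup_accuracy for >2 classes")
    folds, splits = _stratified_folds(y, folds, seed)
    pred = np.empty(y.size, dtype=y.dtype)
    score = np.empty(y.size, dtype=float)
    for train, test in splits:
        model = train_linear_svm(data.subset_samples(train), C=C, standardize=True)
        pred[test] = model.predict(data.values[test])
        score[test] = model.decision(data.values[test])
    pos = y == classes[1]
    sens = float((pred[pos] == classes[1]).mean())
    spec = float((pred[~pos] == classes[0]).mean())
    acc = float((pred == y).mean())
    a, p = auc(score, y)
    confusion = {
        (str(t), str(q)): int(((y == t) & (pred == q)).sum())
        for t in classes
        for q in classes
    }
    return EvaluationReport(
        auc=a,
        auc_p=p,
        roc_points=roc_points(score, y),
        sensitivity=sens,
        specificity=spec,
        overall_accuracy=acc,
        confusion=confusion,
        n_samples=int(y.size),
        folds=folds,
    )


def multigroup_accuracy(
    data: FeatureMatrix,
    signature: "list[str] | None" = None,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> EvaluationReport:
    """One-vs-rest linear SVMs with argmax decision value, under stratified
    seeded CV; micro-averaged (pooled) overall accuracy and the full
    confusion table."""
    if signature is not None:
        idx = [data.feature_names.index(g) for g in signature]
        data = data.subset_features(idx)
    y = data.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    folds, splits = _stratified_folds(y, folds, seed)
    pred = np.empty(y.size, dtype=y.dtype)
    for train, test in splits:
        scores = np.empty((len(test), classes.size))
        for k, cls in enumerate(classes):
            bin_labels = np.where(y[train] == cls, 1, -1)
            sub = FeatureMatrix(
                data.values[train], bin_labels, list(data.feature_names)
            )
            model = train_linear_svm(sub, C=C, standardize=True)
            scores[:, k] = model.decision(data.values[test])
        pred[test] = classes[np.argmax(scores, axis=1)]
    acc = float((pred == y).mean())
    confusion = {
        (str(t), str(q)): int(((y == t) & (pred == q)).sum())
        for t in classes
        for q in classes
    }
    return EvaluationReport(
        overall_accuracy=acc,
        confusion=confusion,
        n_samples=int(y.size),
        folds=folds,
    )
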