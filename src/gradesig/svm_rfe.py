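"""Linear maximum-margin classification and recursive feature elimination.

The classifier is the standard soft-margin linear SVM (the hard-margin
primal is the C -> infinity limit). RFE ranks features by the margin-cost
change J(i) = w_i^2 / 2 of the trained model, eliminates the least useful
feature(s), retrains on the survivors and repeats; the last survivor has
rank 1. Features are standardized (zero mean, unit variance, learned on the
training data only) before each fit so weight magnitudes are comparable
across genes; zero-variance columns standardize to zero and get J = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC


@dataclass
class FeatureMatrix:
    """Samples x features with binary (+1/-1) or categorical labels."""

    values: np.ndarray  # rows = samples, columns = features
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (samples x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("label count must equal sample (row) count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if np.unique(self.labels).size < 2:
            raise ValueError("need at least two classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            self.values[:, idx],
            self.labels,
            [self.feature_names[i] for i in idx],
            self.sample_ids,
        )

    def subset_samples(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            self.values[idx],
            self.labels[idx],
            list(self.feature_names),
            [self.sample_ids[i] for i in idx] if self.sample_ids else None,
        )


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float
    C: float
    feature_names: list[str]
    # standardization parameters applied before the linear map
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    classes: tuple = (-1, 1)

    def decision(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.center is not None:
            X = (X - self.center) / self.scale
        return X @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        d = self.decision(X)
        neg, pos = self.classes
        return np.where(d >= 0, pos, neg)


@dataclass
class EliminationTrace:
    """Per-round record of an RFE run: what was cut and why."""

    rounds: list  # (eliminated feature names, {feature: J}, surviving names)
    final_ranking: list  # best (last-eliminated) first

    def surviving_after(self, n_rounds: int) -> list:
        return list(self.rounds[n_rounds - 1][2]) if n_rounds else list(self.final_ranking)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)  # constant columns -> zeros
    return (X - center) / scale, center, scale


def train_linear_svm(
    data: FeatureMatrix, C: float = 1.0, standardize: bool = False
) -> LinearModel:
    """Fit a soft-margin linear SVM; binary labels only.

    With standardize=False the model is fit on the raw feature scale (the
    analytic small fixtures live there); RFE always standardizes.
    """
    classes = np.unique(data.labels)
    if classes.size != 2:
        raise ValueError(f"binary labels required, got classes {classes}")
    X = data.values
    center = scale = None
    if standardize:
        X, center, scale = _standardize(X)
    # tight tol so margin conditions hold to 1e-6 on separable data; the
    # iteration cap stops the rare non-separable fits where libsvm's dual
    # oscillates for millions of iterations without improving the model
    clf = SVC(kernel="linear", C=C, tol=1e-6, max_iter=1_000_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, data.labels)
    # libsvm orders classes ascending; coef_ is w for decision w.x + b > 0 => classes_[1]
    return LinearModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        C=C,
        feature_names=list(data.feature_names),
        center=center,
        scale=scale,
        classes=tuple(clf.classes_),
    )


def feature_cost(model: LinearModel) -> np.ndarray:
    """Margin-cost change on removing each feature: J(i) = w_i^2 / 2."""
    return 0.5 * model.weights**2


def _n_to_cut(n_surviving: int, half_above: int) -> int:
    if n_surviving > half_above:
        return min(n_surviving // 2, n_surviving - 1)
    return 1


def rfe_rank(
    data: FeatureMatrix,
    C: float = 1.0,
    half_above: int = 100,
    standardize: bool = True,
) -> EliminationTrace:
    """Recursive feature elimination with J(i)-ranking.

    Above ``half_above`` surviving features the lowest-J half is cut per
    round (Guyon-style acceleration); at or below, one per round. Ties in J
    are broken by cutting the larger column index first. Deterministic.
    """
    if data.n_features < 2:
        raise ValueError("RFE needs at least 2 features")
    surviving = list(range(data.n_features))
    rounds = []
    eliminated_order: list[str] = []
    while len(surviving) > 1:
        sub = data.subset_features(surviving)
        model = train_linear_svm(sub, C=C, standardize=standardize)
        J = feature_cost(model)
        k = _n_to_cut(len(surviving), half_above)
        # sort by (J ascending, local index descending) -> stable deterministic cut
        order = sorted(range(len(surviving)), key=lambda i: (J[i], -i))
        cut_local = order[:k]
        cut_names = [data.feature_names[surviving[i]] for i in cut_local]
        keep_local = sorted(set(range(len(surviving))) - set(cut_local))
        j_map = {data.feature_names[surviving[i]]: float(J[i]) for i in range(len(surviving))}
        surviving = [surviving[i] for i in keep_local]
        rounds.append((cut_names, j_map, [data.feature_names[i] for i in surviving]))
        # within a multi-feature cut, the lowest-J (worst) goes to the back
        eliminated_order.extend(
            sorted(cut_names, key=lambda nm: (-j_map[nm], data.feature_names.index(nm)))
        )
    final = [data.feature_names[surviving[0]]] + eliminated_order[::-1]
    return EliminationTrace(rounds=rounds, final_ranking=final)


def rfe_select(
    data: FeatureMatrix,
    target_size: int,
    C: float = 1.0,
    half_above: int = 100,
    standardize: bool = True,
) -> list[str]:
    """Top ``target_size`` features by RFE rank (the surviving set of that
    size, or the smallest surviving trace set >= target_size truncated by
    rank)."""
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if target_size > data.n_features:
        raise ValueError(
            f"target_size {target_size} exceeds feature count {data.n_features}"
        )
    if target_size == data.n_features:
        return list(data.feature_names)
    trace = rfe_rank(data, C=C, half_above=half_above, standardize=standardize)
    ranked = trace.final_ranking[:target_size]
    return ranked
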