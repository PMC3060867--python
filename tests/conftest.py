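import numpy as np
import pytest

from gradesig.datamodel import ExpressionCohort, SampleAnnotation
from gradesig.svm_rfe import FeatureMatrix


def make_cohort(values, grades=None, stages=None, genes=None):
    """Tiny paired cohort: one cancer and one reference column per patient.

    ``values`` is genes x (2 * n_patients), columns ordered C1, R1, C2, R2, ...
    """
    values = np.asarray(values, dtype=float)
    n_pat = values.shape[1] // 2
    grades = grades or ["PD"] * n_pat
    stages = stages or ["II"] * n_pat
    genes = genes or [f"G{i+1}" for i in range(values.shape[0])]
    samples = []
    for p in range(n_pat):
        pid = f"P{p+1}"
        samples.append(SampleAnnotation(f"{pid}_C", pid, "cancer", grades[p], stages[p]))
        samples.append(SampleAnnotation(f"{pid}_R", pid, "reference", grades[p], stages[p]))
    return ExpressionCohort(genes=genes, samples=samples, values=values)


@pytest.fixture
def tiny_cohort():
    """3 genes x 4 patients with hand-set values."""
    rng = np.random.default_rng(42)
    return make_cohort(rng.uniform(5, 9, size=(3, 8)))


def separable_blobs(seed=0, n_per_class=10, n_features=2, sep=3.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(-sep, 1.0, size=(n_per_class, n_features)),
        rng.normal(sep, 1.0, size=(n_per_class, n_features)),
    ])
    y = np.array([-1] * n_per_class + [1] * n_per_class)
    names = [f"f{i}" for i in range(n_features)]
    return FeatureMatrix(X, y, names)


def synergistic_pair_fixture(seed, n=60, n_genes=20, effect=0.8, shared=0.6, noise=0.35):
    """Two genes each weak alone (anti-correlated shared noise) but jointly
    separating the classes; the rest are null."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    X = rng.normal(0, noise, size=(n, n_genes))
    u = rng.normal(0, shared, size=n)
    X[:, 0] += (y == 1) * effect + u
    X[:, 1] += (y == 1) * effect - u
    genes = [f"g{i:02d}" for i in range(n_genes)]
    return FeatureMatrix(X, y, genes), ("g00", "g01")
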