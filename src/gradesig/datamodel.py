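"""Core data containers for paired tumor/reference expression cohorts.

A cohort couples a log2 gene-by-sample expression matrix with sample
annotations carrying the paired (per-patient) structure plus ordinal
tumor grade (WD < MD < PD < UD) and stage (I < II < III < IV) labels.
All downstream statistics work off these containers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRADES = ("WD", "MD", "PD", "UD")
STAGES = ("I", "II", "III", "IV")
GRADE_CODE = {g: i + 1 for i, g in enumerate(GRADES)}
STAGE_CODE = {s: i + 1 for i, s in enumerate(STAGES)}
TISSUES = ("cancer", "reference")


@dataclass(frozen=True)
class SampleAnnotation:
    """One array: which patient, which tissue, and the patient's grade/stage.

    Grade and stage belong to the patient, so both members of a pair carry
    identical values; "NA" marks a missing label.
    """

    sample_id: str
    patient_id: str
    tissue: str
    grade: str = "NA"
    stage: str = "NA"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(
                f"sample {self.sample_id!r}: tissue must be one of {TISSUES}, got {self.tissue!r}"
            )
        if self.grade not in GRADES + ("NA",):
            raise ValueError(
                f"sample {self.sample_id!r}: grade must be one of {GRADES} or 'NA', got {self.grade!r}"
            )
        if self.stage not in STAGES + ("NA",):
            raise ValueError(
                f"sample {self.sample_id!r}: stage must be one of {STAGES} or 'NA', got {self.stage!r}"
            )

    @property
    def grade_code(self) -> int | None:
        return GRADE_CODE.get(self.grade)

    @property
    def stage_code(self) -> int | None:
        return STAGE_CODE.get(self.stage)


@dataclass
class ExpressionCohort:
    """Log2 expression matrix (genes x samples) bound to annotations.

    ``values[i, j]`` is the log2 normalized intensity of ``genes[i]`` in
    ``samples[j]``; columns and annotations are index-aligned.
    """

    genes: list[str]
    samples: list[SampleAnnotation]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise ValueError(f"duplicate gene symbol: {g!r}")
            seen.add(g)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        by_patient: dict[tuple[str, str], str] = {}
        for ann in self.samples:
            key = (ann.patient_id, ann.tissue)
            if key in by_patient:
                raise ValueError(
                    f"patient {ann.patient_id!r} has more than one {ann.tissue} sample "
                    f"({by_patient[key]!r} and {ann.sample_id!r})"
                )
            by_patient[key] = ann.sample_id

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return np.array([s.tissue == tissue for s in self.samples], dtype=bool)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not in cohort: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def complete_pairs(self) -> list[tuple[str, int, int]]:
        """(patient_id, cancer column, reference column) for complete pairs.

        Patients missing either tissue are dropped with a logged warning.
        """
        cancer: dict[str, int] = {}
        reference: dict[str, int] = {}
        order: list[str] = []
        for j, ann in enumerate(self.samples):
            if ann.patient_id not in cancer and ann.patient_id not in reference:
                order.append(ann.patient_id)
            (cancer if ann.tissue == "cancer" else reference)[ann.patient_id] = j
        pairs = []
        for pid in order:
            if pid in cancer and pid in reference:
                pairs.append((pid, cancer[pid], reference[pid]))
            else:
                logger.warning("patient %s lacks a complete cancer/reference pair; dropped", pid)
        return pairs

    def patient_label(self, patient_id: str, axis: str) -> str:
        for ann in self.samples:
            if ann.patient_id == patient_id:
                return ann.grade if axis == "grade" else ann.stage
        raise KeyError(patient_id)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionCohort":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return ExpressionCohort(
            genes=[self.genes[i] for i in idx],
            samples=list(self.samples),
            values=self.values[idx],
        )

    def subset_samples(self, keep: Iterable[int]) -> "ExpressionCohort":
        idx = list(keep)
        return ExpressionCohort(
            genes=list(self.genes),
            samples=[self.samples[j] for j in idx],
            values=self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.genes, name="gene"),
            columns=[s.sample_id for s in self.samples],
        )


@dataclass
class PairedFoldChange:
    """Per-patient log2(cancer) - log2(reference), genes x patients."""

    genes: list[str]
    patients: list[str]
    log2fc: np.ndarray

    def __post_init__(self) -> None:
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        if self.log2fc.shape != (len(self.genes), len(self.patients)):
            raise ValueError("log2fc shape does not match genes x patients")
        if not np.all(np.isfinite(self.log2fc)):
            raise ValueError("log2fc contains non-finite values")

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        return np.array([pos[g] for g in genes], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log2fc, index=pd.Index(self.genes, name="gene"), columns=self.patients
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["sample_id", "patient_id", "tissue", "grade", "stage"]


def load_annotations(path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {missing}")
    anns = []
    for row in df.itertuples(index=False):
        anns.append(
            SampleAnnotation(
                sample_id=row.sample_id,
                patient_id=row.patient_id,
                tissue=row.tissue,
                grade=row.grade or "NA",
                stage=row.stage or "NA",
            )
        )
    ids = [a.sample_id for a in anns]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate sample_id in annotations: {sorted(dupes)}")
    return anns


def load_expression_matrix(path, annotation_path) -> ExpressionCohort:
    """Read an expression TSV (first column "gene") plus its annotation TSV.

    Matrix columns are matched to annotations by sample_id; any column
    without an annotation, duplicated gene symbol or non-numeric cell is
    rejected with a message naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "gene":
        raise ValueError(f"expression file {path}: first column must be 'gene', got {df.columns[0]!r}")
    genes = df["gene"].tolist()
    dupes = {g for g in genes if genes.count(g) > 1}
    if dupes:
        raise ValueError(f"duplicate gene symbol in {path}: {sorted(dupes)}")
    try:
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    anns = load_annotations(annotation_path)
    by_id = {a.sample_id: a for a in anns}
    sample_ids = list(df.columns[1:])
    unmatched = [s for s in sample_ids if s not in by_id]
    if unmatched:
        raise ValueError(f"matrix columns without annotation: {unmatched}")
    samples = [by_id[s] for s in sample_ids]
    return ExpressionCohort(genes=genes, samples=samples, values=values)


def write_cohort(cohort: ExpressionCohort, matrix_path, annotation_path) -> None:
    cohort.to_frame().to_csv(matrix_path, sep="\t", float_format="%.10g")
    pd.DataFrame(
        [
            (s.sample_id, s.patient_id, s.tissue, s.grade, s.stage)
            for s in cohort.samples
        ],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(annotation_path, sep="\t", index=False)


def load_logratio_matrix(path) -> PairedFoldChange:
    """Read an external log2(tumor/normal) ratio TSV (first column "gene")."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene":
        raise ValueError(f"log2-ratio file {path}: first column must be 'gene'")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene symbol in {path}: {dupes}")
    return PairedFoldChange(
        genes=df.index.tolist(), patients=df.columns.tolist(), log2fc=df.to_numpy(float)
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_low_expression(cohort: ExpressionCohort, threshold: float = 4.0) -> ExpressionCohort:
    """Drop genes whose expression never reaches ``threshold`` in either tissue.

    A gene is removed only if its maximum over cancer samples and its maximum
    over reference samples are both strictly below the threshold (a maximum of
    exactly 4 is kept). Gene order is preserved; idempotent.
    """
    cancer = cohort.tissue_mask("cancer")
    reference = cohort.tissue_mask("reference")
    if not cancer.any() or not reference.any():
        raise ValueError("cohort must contain at least one cancer and one reference sample")
    max_cancer = cohort.values[:, cancer].max(axis=1)
    max_reference = cohort.values[:, reference].max(axis=1)
    keep = (max_cancer >= threshold) | (max_reference >= threshold)
    logger.info(
        "low-expression filter (threshold %.3g): kept %d of %d genes",
        threshold, int(keep.sum()), cohort.n_genes,
    )
    return cohort.subset_genes(keep)


def compute_paired_fold_changes(cohort: ExpressionCohort) -> PairedFoldChange:
    """Per-patient log2 fold change, one column per complete pair.

    Since the data are log2 scale, a k-fold change corresponds to an absolute
    per-pair difference of at least log2(k).
    """
    pairs = cohort.complete_pairs()
    if not pairs:
        raise ValueError("no complete cancer/reference pairs in cohort")
    patients = [p for p, _, _ in pairs]
    fc = np.column_stack(
        [cohort.values[:, jc] - cohort.values[:, jr] for _, jc, jr in pairs]
    )
    return PairedFoldChange(genes=list(cohort.genes), patients=patients, log2fc=fc)
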