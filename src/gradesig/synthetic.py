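"""Synthetic paired tumor/reference cohorts with planted ground truth.

The generator is an additive Gaussian model on the log2 scale: each gene has
a baseline level, each patient a shared random offset (so the paired design
carries real within-patient correlation), and the cancer sample of a patient
adds a gene- and group-dependent effect:

    reference = mu_g + a_p + eps
    cancer    = mu_g + a_p + delta_g(grade, stage) + eps

Planted gene classes:

* DE genes — delta is a fixed signed log2 effect for every cancer sample.
* Trend genes — delta = sign * step * grade_code, so per-grade cancer means
  are strictly monotone across WD < MD < PD < UD.
* Signature genes — delta is applied only in the target group of a named
  contrast (e.g. only high-grade patients), making the gene discriminative
  for that contrast but not globally.
* Null genes — delta = 0; the majority, so calibration is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import (
    GRADE_CODE,
    GRADES,
    STAGES,
    ExpressionCohort,
    SampleAnnotation,
)

#: Contrast name -> (axis, set of target levels). Signature genes planted for
#: a contrast shift only cancer samples of patients in the target set.
CONTRAST_TARGETS = {
    "grade-high-vs-low": ("grade", {"PD", "UD"}),
    "grade-low-vs-high": ("grade", {"WD", "MD"}),
    "stage-early-vs-advanced": ("stage", {"I", "II"}),
    "stage-advanced-vs-early": ("stage", {"III", "IV"}),
    "grade-WD": ("grade", {"WD"}),
    "grade-MD": ("grade", {"MD"}),
    "grade-PD": ("grade", {"PD"}),
    "grade-UD": ("grade", {"UD"}),
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 2000
    patients_per_grade: dict = field(
        default_factory=lambda: {"WD": 8, "MD": 9, "PD": 35, "UD": 2}
    )
    patients_per_stage: dict | None = None
    n_de_genes: int = 0
    de_effect: float = 1.5
    n_trend_genes: int = 0
    trend_step: float = 0.5
    n_signature_genes: dict = field(default_factory=dict)
    signature_effect: float = 1.2
    baseline_mean_range: tuple[float, float] = (5.0, 12.0)
    gene_sd: float = 0.5
    patient_sd: float = 0.5
    noise_sd: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_genes, self.n_de_genes, self.n_trend_genes]
        counts += list(self.n_signature_genes.values())
        if any(c < 0 for c in counts):
            raise ValueError("all gene counts must be >= 0")
        planted = self.n_de_genes + self.n_trend_genes + sum(self.n_signature_genes.values())
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        for sd in (self.gene_sd, self.patient_sd, self.noise_sd):
            if sd <= 0:
                raise ValueError("standard deviations must be > 0")
        for contrast in self.n_signature_genes:
            if contrast not in CONTRAST_TARGETS:
                raise ValueError(f"unknown contrast {contrast!r}")
        if any(g not in GRADES for g in self.patients_per_grade):
            raise ValueError("patients_per_grade keys must be grades WD/MD/PD/UD")
        if self.patients_per_stage is not None and any(
            s not in STAGES for s in self.patients_per_stage
        ):
            raise ValueError("patients_per_stage keys must be stages I/II/III/IV")

    @property
    def n_patients(self) -> int:
        return sum(self.patients_per_grade.values())


@dataclass
class GroundTruth:
    """What was planted where: gene -> class, effect, and per-grade profiles."""

    de_genes: dict  # gene -> signed log2 effect
    trend_genes: dict  # gene -> {"sign": +-1, "step": float, "profile": tuple of 4 means}
    signature_genes: dict  # contrast -> {gene -> signed effect}
    null_genes: set

    def planted(self) -> set:
        out = set(self.de_genes) | set(self.trend_genes)
        for d in self.signature_genes.values():
            out |= set(d)
        return out


def default_config(seed: int = 0) -> SyntheticConfig:
    """The study-sized default: 54 patients (8 WD, 9 MD, 35 PD, 2 UD), 108
    arrays, and a 2000-gene panel (a desk-scale stand-in for genome-wide
    profiling that keeps the mostly-null regime)."""
    return SyntheticConfig(seed=seed)


def generate_cohort(config: SyntheticConfig) -> tuple[ExpressionCohort, GroundTruth]:
    """Draw one cohort plus its ground truth; identical config => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # Patients in grade order; stages assigned independently of grade.
    grades: list[str] = []
    for g in GRADES:
        grades += [g] * config.patients_per_grade.get(g, 0)
    n_pat = len(grades)
    if n_pat == 0:
        raise ValueError("no patients configured")
    if config.patients_per_stage is not None:
        stages: list[str] = []
        for s in STAGES:
            stages += [s] * config.patients_per_stage.get(s, 0)
        if len(stages) != n_pat:
            raise ValueError(
                f"patients_per_stage sums to {len(stages)} but there are {n_pat} patients"
            )
        stages = list(rng.permutation(stages))
    else:
        stages = list(rng.choice(STAGES, size=n_pat))

    width = len(str(n_pat))
    patient_ids = [f"P{i + 1:0{width}d}" for i in range(n_pat)]

    # Gene roles, assigned from the front of a shuffled symbol list.
    width_g = len(str(config.n_genes))
    genes = [f"G{i + 1:0{width_g}d}" for i in range(config.n_genes)]
    order = rng.permutation(config.n_genes)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [genes[i] for i in order[cursor : cursor + k]]
        cursor += k
        return out

    de = take(config.n_de_genes)
    trend = take(config.n_trend_genes)
    signature = {c: take(k) for c, k in sorted(config.n_signature_genes.items())}

    de_signs = rng.choice([-1.0, 1.0], size=len(de))
    trend_signs = rng.choice([-1.0, 1.0], size=len(trend))
    sig_signs = {c: rng.choice([-1.0, 1.0], size=len(gs)) for c, gs in signature.items()}

    gene_pos = {g: i for i, g in enumerate(genes)}
    # delta[i, p]: cancer-only shift of gene i in patient p
    delta = np.zeros((config.n_genes, n_pat))
    for g, s in zip(de, de_signs):
        delta[gene_pos[g], :] = s * config.de_effect
    grade_codes = np.array([GRADE_CODE[g] for g in grades], dtype=float)
    for g, s in zip(trend, trend_signs):
        delta[gene_pos[g], :] = s * config.trend_step * grade_codes
    for contrast, gs in signature.items():
        axis, targets = CONTRAST_TARGETS[contrast]
        labels = grades if axis == "grade" else stages
        in_target = np.array([lab in targets for lab in labels])
        for g, s in zip(gs, sig_signs[contrast]):
            delta[gene_pos[g], in_target] = s * config.signature_effect

    lo, hi = config.baseline_mean_range
    mu = rng.uniform(lo, hi, size=config.n_genes)
    a = rng.normal(0.0, config.patient_sd, size=n_pat)
    base = mu[:, None] + a[None, :]
    ref = base + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_pat))
    can = base + delta + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_pat))

    samples: list[SampleAnnotation] = []
    cols: list[np.ndarray] = []
    for p in range(n_pat):
        samples.append(
            SampleAnnotation(f"{patient_ids[p]}_C", patient_ids[p], "cancer", grades[p], stages[p])
        )
        cols.append(can[:, p])
        samples.append(
            SampleAnnotation(f"{patient_ids[p]}_R", patient_ids[p], "reference", grades[p], stages[p])
        )
        cols.append(ref[:, p])
    cohort = ExpressionCohort(genes=genes, samples=samples, values=np.column_stack(cols))

    truth = GroundTruth(
        de_genes={g: float(s * config.de_effect) for g, s in zip(de, de_signs)},
        trend_genes={
            g: {
                "sign": float(s),
                "step": config.trend_step,
                "profile": tuple(float(s * config.trend_step * c) for c in (1, 2, 3, 4)),
            }
            for g, s in zip(trend, trend_signs)
        },
        signature_genes={
            c: {g: float(s * config.signature_effect) for g, s in zip(gs, sig_signs[c])}
            for c, gs in signature.items()
        },
        null_genes=set(genes) - set(de) - set(trend) - {g for gs in signature.values() for g in gs},
    )
    return cohort, truth


def truth_table(truth: GroundTruth) -> "list[tuple[str, str, float]]":
    """(gene, class, effect) rows for serialization."""
    rows: list[tuple[str, str, float]] = []
    for g, e in sorted(truth.de_genes.items()):
        rows.append((g, "de", e))
    for g, info in sorted(truth.trend_genes.items()):
        rows.append((g, "trend", info["sign"] * info["step"]))
    for contrast, d in sorted(truth.signature_genes.items()):
        for g, e in sorted(d.items()):
            rows.append((g, f"signature:{contrast}", e))
    for g in sorted(truth.null_genes):
        rows.append((g, "null", 0.0))
    return rows
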