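"""End-to-end orchestration of the grade and stage analyses.

The grade pipeline: low-expression filter -> per-grade differential
expression (paired Wilcoxon strategy and K_exp count strategy) with
core/extended set summaries -> ordinal trend screen -> ensemble SVM-RFE
selection for the binary high-vs-low grade contrast (EFC features) and the
five-way grades-plus-control classification (REL features) -> exhaustive
small-panel search over DE candidates -> cross-validated evaluation
reports. The stage pipeline mirrors it with early (I+II) vs advanced
(III+IV) contrasts and a three-group (early/advanced/control) report.

Contrast conventions: "high grade" = PD+UD, "low grade" = WD+MD;
"early stage" = I+II, "advanced" = III+IV. Feature modes: REL uses raw
log2 levels of individual samples; EFC uses per-patient log2 fold changes
(one observation per pair), so control samples only exist in REL mode.

Saved signatures can be applied to external per-patient log2(tumor/normal)
ratio matrices; only EFC-mode signatures are applicable there.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import diffexpr, trend
from .datamodel import (
    GRADES,
    STAGES,
    ExpressionCohort,
    PairedFoldChange,
    compute_paired_fold_changes,
    filter_low_expression,
)
from .evaluation import cross_validate, evaluate_single_gene, multigroup_accuracy
from .selection import (
    Signature,
    consensus_signature,
    exhaustive_k_search,
    group_signature,
    make_split_plan,
)
from .svm_rfe import FeatureMatrix

logger = logging.getLogger(__name__)

GRADE_CONTRASTS = {"high": {"PD", "UD"}, "low": {"WD", "MD"}}
STAGE_CONTRASTS = {"early": {"I", "II"}, "advanced": {"III", "IV"}}


@dataclass
class PipelineConfig:
    fc_threshold: float = 2.0
    alpha: float = 0.05
    filter_threshold: float = 4.0
    n_splits: int = 500
    n_groups: int = 10
    vote_threshold: float = 0.7
    C: float = 1.0
    target_size: int = 10
    prescreen_top: int | None = 100
    combo_k: int = 2
    combo_candidates: int = 20
    folds: int = 5
    trend_feature: str = "EFC"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Feature-matrix construction
# ---------------------------------------------------------------------------

def patient_axis_labels(cohort: ExpressionCohort, patients: list, axis: str) -> list:
    return [cohort.patient_label(p, axis) for p in patients]


def efc_feature_matrix(
    cohort: ExpressionCohort, axis: str, positive: set, negative: set
) -> FeatureMatrix:
    """One row per patient pair (log2 fold changes), labels +1 for patients
    whose grade/stage is in ``positive``, -1 for ``negative``; others dropped."""
    pairs = compute_paired_fold_changes(cohort)
    labels, keep = [], []
    for j, p in enumerate(pairs.patients):
        lab = cohort.patient_label(p, axis)
        if lab in positive:
            labels.append(1)
            keep.append(j)
        elif lab in negative:
            labels.append(-1)
            keep.append(j)
    if len(set(labels)) < 2:
        raise ValueError(f"contrast needs patients on both sides of the {axis} split")
    return FeatureMatrix(
        values=pairs.log2fc[:, keep].T,
        labels=np.array(labels),
        feature_names=list(pairs.genes),
        sample_ids=[pairs.patients[j] for j in keep],
    )


def rel_feature_matrix(
    cohort: ExpressionCohort, axis: str | None = None, include_control: bool = True
) -> FeatureMatrix:
    """One row per sample (raw log2 levels). Cancer samples are labelled by
    their grade/stage (or "cancer" when axis is None); reference samples are
    labelled "control" when included."""
    rows, labels, ids = [], [], []
    for j, ann in enumerate(cohort.samples):
        if ann.tissue == "cancer":
            lab = getattr(ann, axis) if axis else "cancer"
            if lab == "NA":
                continue
        elif include_control:
            lab = "control"
        else:
            continue
        rows.append(cohort.values[:, j])
        labels.append(lab)
        ids.append(ann.sample_id)
    return FeatureMatrix(
        values=np.vstack(rows),
        labels=np.array(labels, dtype=object),
        feature_names=list(cohort.genes),
        sample_ids=ids,
    )


def rel_binary_matrix(
    cohort: ExpressionCohort, axis: str, positive: set, negative: set
) -> FeatureMatrix:
    """Cancer samples only, +1/-1 by group membership, raw log2 levels."""
    rows, labels, ids = [], [], []
    for j, ann in enumerate(cohort.samples):
        if ann.tissue != "cancer":
            continue
        lab = getattr(ann, axis)
        if lab in positive:
            rows.append(cohort.values[:, j]); labels.append(1); ids.append(ann.sample_id)
        elif lab in negative:
            rows.append(cohort.values[:, j]); labels.append(-1); ids.append(ann.sample_id)
    if len(set(labels)) < 2:
        raise ValueError(f"contrast needs samples on both sides of the {axis} split")
    return FeatureMatrix(np.vstack(rows), np.array(labels), list(cohort.genes), ids)


def grouped_rel_matrix(
    cohort: ExpressionCohort, axis: str, grouping: dict
) -> FeatureMatrix:
    """REL matrix whose cancer labels are collapsed through ``grouping``
    (level -> group name), keeping "control" rows."""
    base = rel_feature_matrix(cohort, axis=axis, include_control=True)
    labels, keep = [], []
    for i, lab in enumerate(base.labels):
        if lab == "control":
            labels.append("control"); keep.append(i)
        elif lab in grouping:
            labels.append(grouping[lab]); keep.append(i)
    fm = base.subset_samples(keep)
    fm.labels = np.array(labels, dtype=object)
    return fm


# ---------------------------------------------------------------------------
# Shared stages
# ---------------------------------------------------------------------------

def _per_group_de(cohort: ExpressionCohort, axis: str, cfg: PipelineConfig) -> dict:
    levels = GRADES if axis == "grade" else STAGES
    out = {}
    for lev in levels:
        patients = sorted(
            {s.patient_id for s in cohort.samples if getattr(s, axis) == lev}
        )
        if len(patients) < 2:
            logger.warning("%s %s has %d patients; DE skipped", axis, lev, len(patients))
            continue
        results = diffexpr.call_de_genes(
            cohort, patients=patients, fc_threshold=cfg.fc_threshold, alpha=cfg.alpha
        )
        out[lev] = {
            "results": results,
            "summary": diffexpr.core_extended_sets(results, group=lev),
        }
        logger.info(
            "%s %s: %d extended / %d core DE genes",
            axis, lev, len(out[lev]["summary"].extended_set), len(out[lev]["summary"].core_set),
        )
    return out


def _ensemble_signature(
    fm: FeatureMatrix, cfg: PipelineConfig, contrast: str, feature_mode: str
) -> tuple[Signature, list, dict]:
    plan = make_split_plan(
        fm.labels, n_splits=cfg.n_splits, n_groups=cfg.n_groups, seed=cfg.seed
    )
    group_sigs = []
    for g in range(cfg.n_groups):
        sig = group_signature(
            fm,
            plan.group(g),
            target_size=cfg.target_size,
            vote_threshold=cfg.vote_threshold,
            C=cfg.C,
            prescreen_top=cfg.prescreen_top,
            contrast=contrast,
            feature_mode=feature_mode,
        )
        group_sigs.append(sig)
    consensus, report = consensus_signature(group_sigs)
    consensus.seed = cfg.seed
    return consensus, group_sigs, report


def _combo_candidates(de_by_group: dict, fm: FeatureMatrix, n: int) -> list:
    """Top-n DE candidates (by best per-group count-test p) present in fm."""
    best_p: dict[str, float] = {}
    for info in de_by_group.values():
        for r in info["results"]:
            if r.called_wilcoxon or r.called_count:
                p = min(r.p_wilcoxon_paired, r.p_count)
                if p < best_p.get(r.gene, np.inf):
                    best_p[r.gene] = p
    in_fm = set(fm.feature_names)
    ranked = sorted((g for g in best_p if g in in_fm), key=lambda g: (best_p[g], g))
    return ranked[:n]


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def run_grade_pipeline(
    cohort: ExpressionCohort, config: PipelineConfig | None = None
) -> dict:
    """Full grade analysis; returns a result bundle keyed by stage name."""
    cfg = config or PipelineConfig()
    bundle: dict = {"config": cfg.to_dict(), "axis": "grade"}
    cohort = filter_low_expression(cohort, cfg.filter_threshold)
    bundle["n_genes_after_filter"] = cohort.n_genes

    de = _per_group_de(cohort, "grade", cfg)
    bundle["de_by_grade"] = de
    bundle["extended_union"] = sorted(
        set().union(*(info["summary"].extended_set for info in de.values()))
    ) if de else []

    bundle["trend"] = trend.find_trend_genes(
        cohort, axis="grade", feature=cfg.trend_feature, alpha=cfg.alpha
    )

    fm_efc = efc_feature_matrix(
        cohort, "grade", GRADE_CONTRASTS["high"], GRADE_CONTRASTS["low"]
    )
    sig, group_sigs, consistency = _ensemble_signature(
        fm_efc, cfg, "grade-high-vs-low", "EFC"
    )
    bundle["binary_signature"] = sig
    bundle["group_signatures"] = group_sigs
    bundle["consistency"] = consistency
    if sig.genes:
        bundle["binary_report"] = cross_validate(
            fm_efc, sig.genes, folds=cfg.folds, seed=cfg.seed, C=cfg.C
        )

    fm_rel = rel_feature_matrix(cohort, axis="grade", include_control=True)
    five_way_sig, _, _ = _ensemble_signature(
        rel_binary_matrix(cohort, "grade", GRADE_CONTRASTS["high"], GRADE_CONTRASTS["low"]),
        cfg, "grade-high-vs-low", "REL",
    )
    bundle["five_way_signature"] = five_way_sig
    if five_way_sig.genes:
        bundle["five_way_report"] = multigroup_accuracy(
            fm_rel, five_way_sig.genes, folds=cfg.folds, seed=cfg.seed, C=cfg.C
        )

    candidates = _combo_candidates(de, fm_efc, cfg.combo_candidates)
    if len(candidates) >= cfg.combo_k:
        bundle["combos"] = exhaustive_k_search(
            fm_efc, candidates, k=cfg.combo_k, cv_folds=cfg.folds, seed=cfg.seed, C=cfg.C
        )
        bundle["combo_candidates"] = candidates

    # single-gene discriminators per grade (REL), Table-1 style
    bundle["single_gene"] = single_gene_tables(cohort, "grade", top=3)
    return bundle


def run_stage_pipeline(
    cohort: ExpressionCohort, config: PipelineConfig | None = None
) -> dict:
    """Stage analysis: early (I+II) vs advanced (III+IV) signatures in both
    REL and EFC modes, plus the 3-group early/advanced/control report."""
    cfg = config or PipelineConfig()
    stages_present = {s.stage for s in cohort.samples} - {"NA"}
    if not stages_present:
        raise ValueError("cohort has no stage annotations (column 'stage' all NA)")
    bundle: dict = {"config": cfg.to_dict(), "axis": "stage"}
    cohort = filter_low_expression(cohort, cfg.filter_threshold)
    bundle["n_genes_after_filter"] = cohort.n_genes

    de = _per_group_de(cohort, "stage", cfg)
    bundle["de_by_stage"] = de

    bundle["trend"] = trend.find_trend_genes(
        cohort, axis="stage", feature=cfg.trend_feature, alpha=cfg.alpha
    )

    fm_efc = efc_feature_matrix(
        cohort, "stage", STAGE_CONTRASTS["early"], STAGE_CONTRASTS["advanced"]
    )
    sig_efc, _, _ = _ensemble_signature(fm_efc, cfg, "stage-early-vs-advanced", "EFC")
    bundle["efc_signature"] = sig_efc
    if sig_efc.genes:
        bundle["efc_report"] = cross_validate(
            fm_efc, sig_efc.genes, folds=cfg.folds, seed=cfg.seed, C=cfg.C
        )

    fm_rel_bin = rel_binary_matrix(
        cohort, "stage", STAGE_CONTRASTS["early"], STAGE_CONTRASTS["advanced"]
    )
    sig_rel, _, _ = _ensemble_signature(fm_rel_bin, cfg, "stage-early-vs-advanced", "REL")
    bundle["rel_signature"] = sig_rel

    grouping = {"I": "early", "II": "early", "III": "advanced", "IV": "advanced"}
    fm3 = grouped_rel_matrix(cohort, "stage", grouping)
    three_way_genes = sig_rel.genes or sig_efc.genes
    if three_way_genes:
        bundle["three_group_report"] = multigroup_accuracy(
            fm3, three_way_genes, folds=cfg.folds, seed=cfg.seed, C=cfg.C
        )

    # Table-2 style single-gene tables on an identical gene universe
    bundle["single_gene_rel"] = single_gene_tables(cohort, "stage", top=3, feature="REL")
    bundle["single_gene_efc"] = single_gene_tables(cohort, "stage", top=3, feature="EFC")
    return bundle


def single_gene_tables(
    cohort: ExpressionCohort, axis: str, top: int = 3, feature: str = "REL"
) -> dict:
    """Per-level top single-gene discriminators (level vs all the rest,
    controls included for REL), ranked by AUC; each entry carries AUC, the
    rank-sum p, the Youden cutoff and its sensitivity/specificity."""
    levels = GRADES if axis == "grade" else STAGES
    if feature == "REL":
        fm = rel_feature_matrix(cohort, axis=axis, include_control=True)
    else:
        pairs = compute_paired_fold_changes(cohort)
        fm = FeatureMatrix(
            pairs.log2fc.T,
            np.array([cohort.patient_label(p, axis) for p in pairs.patients], dtype=object),
            list(pairs.genes),
            list(pairs.patients),
        )
    out = {}
    for lev in levels:
        y = (fm.labels == lev).astype(int)
        if y.sum() == 0 or y.sum() == y.size:
            continue
        rows = []
        for i, gene in enumerate(fm.feature_names):
            rep = evaluate_single_gene(fm.values[:, i], y)
            rows.append((gene, rep))
        rows.sort(key=lambda t: (-(t[1].auc if t[1].auc >= 0.5 else 1 - t[1].auc), t[0]))
        out[lev] = rows[:top]
    return out


def apply_signature(
    signature: Signature,
    logratio: PairedFoldChange,
    labels,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    min_overlap: float = 0.5,
):
    """Score a saved EFC signature on an external log2(tumor/normal) matrix.

    Signature genes missing from the matrix are imputed as 0 log-ratio (no
    change) with a logged list; below ``min_overlap`` coverage the run is
    refused. The classifier is refit by cross-validation on the provided
    per-patient labels.
    """
    if signature.feature_mode != "EFC":
        raise ValueError(
            "only EFC-mode signatures apply to log2-ratio data; "
            f"this signature is {signature.feature_mode}-mode (raw expression levels)"
        )
    present = [g for g in signature.genes if g in set(logratio.genes)]
    overlap = len(present) / len(signature.genes) if signature.genes else 0.0
    if overlap < min_overlap:
        raise ValueError(
            f"only {overlap:.0%} of signature genes are in the matrix "
            f"(minimum {min_overlap:.0%})"
        )
    missing = [g for g in signature.genes if g not in set(logratio.genes)]
    if missing:
        logger.warning("imputing 0 log-ratio for %d missing genes: %s", len(missing), missing)
    X = np.zeros((len(logratio.patients), len(signature.genes)))
    gidx = {g: i for i, g in enumerate(logratio.genes)}
    for k, g in enumerate(signature.genes):
        if g in gidx:
            X[:, k] = logratio.log2fc[gidx[g]]
    fm = FeatureMatrix(X, np.asarray(labels), list(signature.genes), list(logratio.patients))
    return cross_validate(fm, folds=folds, seed=seed, C=C)


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def signature_to_json(sig: Signature) -> str:
    return json.dumps(
        {
            "schema": "gradesig/signature/v1",
            "genes": sig.genes,
            "feature_mode": sig.feature_mode,
            "contrast": sig.contrast,
            "vote_fraction": sig.vote_fraction,
            "seed": sig.seed,
            "params": sig.params,
        },
        indent=2,
    )


def signature_from_json(text: str) -> Signature:
    obj = json.loads(text)
    return Signature(
        genes=obj["genes"],
        feature_mode=obj["feature_mode"],
        contrast=obj["contrast"],
        vote_fraction=obj.get("vote_fraction", {}),
        seed=obj.get("seed"),
        params=obj.get("params", {}),
    )


def save_signature(sig: Signature, path) -> None:
    Path(path).write_text(signature_to_json(sig))


def load_signature(path) -> Signature:
    return signature_from_json(Path(path).read_text())
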