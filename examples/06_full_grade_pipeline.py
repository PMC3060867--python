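"""Run the full grade analysis end to end on a planted synthetic cohort.

Stages: low-expression filter -> per-grade DE (two strategies, core and
extended sets) -> monotone trend screen -> ensemble SVM-RFE signatures
(binary high-vs-low on fold changes; five-way grades+control on raw
levels) -> exhaustive pair search over DE candidates -> CV reports.
"""

from gradesig import PipelineConfig, SyntheticConfig, generate_cohort
from gradesig.pipeline import run_grade_pipeline

cohort, truth = generate_cohort(
    SyntheticConfig(
        n_genes=800,
        n_de_genes=20, de_effect=1.5,
        n_trend_genes=10, trend_step=0.5,
        n_signature_genes={"grade-high-vs-low": 8}, signature_effect=1.2,
        noise_sd=0.3, seed=11,
    )
)
config = PipelineConfig(n_splits=50, n_groups=5, target_size=20,
                        prescreen_top=80, seed=11)
bundle = run_grade_pipeline(cohort, config)

print(f"genes after low-expression filter: {bundle['n_genes_after_filter']}")
for grade, info in bundle["de_by_grade"].items():
    s = info["summary"]
    print(f"  {grade}: extended {len(s.extended_set)}, core {len(s.core_set)}")
print(f"trend genes: {len(bundle['trend'])}")
sig = bundle["binary_signature"]
planted = set(truth.signature_genes["grade-high-vs-low"])
print(f"binary signature ({sig.feature_mode}): {len(sig.genes)} genes, "
      f"recall {len(set(sig.genes) & planted)}/{len(planted)}")
print(f"binary CV accuracy: {bundle['binary_report'].overall_accuracy:.3f}")
if "five_way_report" in bundle:
    print(f"five-way (grades+control) accuracy: "
          f"{bundle['five_way_report'].overall_accuracy:.3f}")
if "combos" in bundle:
    best = bundle["combos"][0]
    print(f"best DE-gene pair {best.combo}: cv_accuracy={best.cv_accuracy:.3f}")
# Every stage of the published analysis runs on this desk-scale cohort; the
# same calls accept any real log2 expression TSV plus annotations.
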