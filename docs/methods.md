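# Methods

## Data model

A cohort is a log2 gene × sample matrix bound to sample annotations. Each
patient contributes at most one cancer and one reference array; grade
(WD < MD < PD < UD, coded 1–4) and stage (I–IV, coded 1–4) attach to the
patient, so both members of a pair carry the same labels. Patients missing
either array are dropped from paired statistics with a logged warning —
no imputation, since every paired test assumes complete pairs.

The low-expression filter removes a gene only when its maximum over all
cancer samples **and** its maximum over all reference samples are both
strictly below the threshold (default 4 on the log2 scale); a maximum of
exactly 4 is kept. The maxima are taken per tissue group over all samples,
not per pair, and the filter is idempotent.

"k-fold change" always means an absolute per-pair log2 difference of at
least log2 k, since the data are log2-transformed upstream (the package
consumes post-RMA matrices; probe-level preprocessing is out of scope).

## Differential expression

Two strategies are computed independently per gene:

* **Paired strategy.** Two-sided Wilcoxon signed-rank test on the per-pair
  log2 fold changes (zeros dropped by the Wilcoxon convention; exact
  enumeration null for n ≤ 25 without tied magnitudes, tie-corrected
  normal approximation otherwise). A gene is *called* when additionally
  |mean log2FC| ≥ log2(fc_threshold) — the fold-change requirement is
  evaluated at the gene level on the mean per-pair change, not per pair.
* **Count strategy.** K_exp, the number of pairs whose fold change exceeds
  the threshold in one direction, against the exact upper tail of
  Binomial(n_pairs, null_prob). Both one-sided tests (up, down) are run
  and the smaller-p side is reported. The default null_prob = ½ is a
  sign-test null: under any per-pair distribution symmetric about zero the
  probability of a >2-fold change in a fixed direction is well below ½, so
  the test is conservative for that event. null_prob is exposed for users
  who prefer a calibrated exceedance probability.

The unpaired Mann–Whitney test (cancer vs reference pooled) is reported
alongside (exact for small tie-free groups). P-values are deliberately not
adjusted for multiple testing by default — the calls feed a subsequent
classification step where losing weak candidates is costlier than false
positives — but a Benjamini–Hochberg flag is available.

Core set = genes called by both strategies; extended set = by at least
one. Grade/stage-independent genes are those called in every per-grade and
per-stage analysis with the same direction everywhere.

## Trend screening

For each gene, expression is averaged within each ordinal level — either
cancer-sample levels (REL) or per-pair fold changes (EFC; the default,
since "expression change" across grades is most naturally a fold change
and the patient baseline cancels) — and the m-point profile is correlated
with the codes 1..m by Spearman's ρ (midranks under ties). The p-value is
the exact one-sided tail over all m! equally likely orderings of the
profile, computed by enumeration for m ≤ 7; profiles with the same rank
pattern share a cached p. A "perfect" trend requires |ρ| = 1, p < α and a
strictly monotone profile, so with four grades p = 1/24 ≈ 0.042 and the
joint criterion is attainable at α = 0.05.

The m! null is exact only when the per-level means are exchangeable, i.e.
the levels hold equal sample counts. Under the study's unbalanced design
(8/9/35/2), the noisy 2-patient UD mean inflates the chance rate of
monotone profiles above 2/4!; calibration checks therefore use a balanced
54-patient design (13/13/14/14), and levels with fewer than 3 samples are
flagged in the log.

## Linear SVM and RFE

The classifier is the soft-margin linear SVM (libsvm via scikit-learn);
the hard-margin formulation is its C → ∞ limit. Solver tolerance is 1e-6
so that on separable data with large C every training point satisfies
y(w·x + b) ≥ 1 − 1e-6; an iteration cap (10^6) stops the rare
non-separable fits where the dual oscillates indefinitely without
improving the returned model. C defaults to 1.0 and is exposed
throughout; for selecting an exact panel among strongly redundant
informative genes a smaller C (stronger regularization) ranks more
stably, because near the hard margin redundant features share weight and
individually look dispensable.

RFE ranks features by J(i) = w_i²/2 of the model trained on the current
survivors, eliminates the lowest-J feature, and retrains. Above 100
surviving features the lowest-J half is cut per round (Guyon-style
acceleration); at or below, one per round, so the endgame matches
one-at-a-time elimination. Ties in J cut the larger column index first —
deterministic and documented. Features are standardized (mean 0, variance
1, parameters learned on the training data of the current fit only)
before every SVM fit, since raw weight magnitudes are scale-confounded;
zero-variance columns standardize to zero and get J = 0, so constant
features always leave first.

## Ensemble selection

Sample half-splitting is stratified by class (both classes present in
every half; odd class counts alternate the extra sample across splits so
the halves stay within one sample of each other), seeded, and grouped:
the default 500 splits in 10 groups of 50 mirror the resampling design
the analysis is built around; desk-scale runs use 100 splits in 10 groups
of 10.

Within a group, RFE runs on each split's training half. To keep
genome-scale inputs tractable, candidates are first pre-screened per
split to the top N (default 100) genes by Mann–Whitney p **computed on
the training half only** — test halves are never touched during
selection, only for scoring candidate subset sizes. The per-split
selection size is deliberately set above the expected panel size
(default 20 for a ~10-gene signature): votes, not the RFE cut, decide
membership, and a tight target makes one RFE miss cost a true gene its
vote. A gene enters the group signature at vote fraction ≥ 0.7 (the
threshold is clamped to [0,1]; at 0 the signature is the union, at 1
unanimity). Groups merge by strict majority (> half of the groups);
the consistency report carries the pairwise Jaccard matrix and per-gene
support. An empty signature is a warning, not an error.

`best_rfe_classifier` scores candidate subset sizes by mean test-half
accuracy over a group's splits and refits the argmax size (ties → smaller
subset) on all samples.

The exhaustive k-gene search enumerates every combination of the
candidate list (budget-guarded, default 10^6), scoring each by seeded
stratified 5-fold cross-validated linear-SVM accuracy; output is sorted
by accuracy, ties lexicographic, and its length is exactly C(n, k).

## Evaluation

AUC is the Mann–Whitney probability estimate (ties 0.5) with a two-sided
rank-sum p between the score distributions. For group-vs-rest single-gene
tables the compared groups are independent samples of unequal size, so a
signed-rank (paired) test is not applicable and the rank-sum test is used
throughout. Cutoffs are midpoints between adjacent distinct scores,
chosen to maximize Youden's J; both orientations are scanned so markers
running low in the positive class are handled, and constant scores return
a degenerate-input flag. Cross-validation is stratified and seeded, folds
reduce with a warning when the smallest class is smaller than the fold
count, and held-out predictions are pooled (micro-averaged) — accuracy,
sensitivity (w.r.t. the contrast's target class), specificity, AUC on
pooled decision values, and the full confusion table. Multi-group
classification uses one-vs-rest linear SVMs with argmax decision value.

For external validation, only fold-change-mode (EFC) signatures apply to
log2(tumor/normal) ratio matrices; raw-level (REL) signatures are
refused with an explanatory error. Signature genes missing from the
matrix are imputed at 0 log-ratio (no change) with a logged list, and a
run is refused below 50% gene overlap.

## Pipelines and contrasts

The binary grade contrast is high = {PD, UD} vs low = {WD, MD}; staging
uses early = {I, II} vs advanced = {III, IV}. The binary grade signature
uses EFC features (fold change against the patient's own reference); the
five-way (four grades + control) and three-way (early/advanced/control)
classifications use REL features, since control samples have no fold
change. Every result bundle embeds its full configuration and seed, and
re-running a configuration reproduces the bundle exactly.

## Synthetic cohorts

The generator is an additive Gaussian model on the log2 scale:
reference = μ_g + a_p + ε and cancer = μ_g + a_p + Δ_g + ε, with gene
baselines μ_g ~ Uniform(5, 12), patient effects a_p ~ N(0, 0.5²) and
noise ε ~ N(0, noise_sd²), noise_sd default 0.35. The shared patient
effect gives the paired design real within-patient correlation, making
paired tests strictly more powerful than unpaired ones, as the design
assumes. Planted classes: DE genes (Δ = ±effect in every cancer sample),
trend genes (Δ = ±step × grade code, strictly monotone per-grade means),
signature genes (Δ only in the target group of a named contrast), and
nulls (Δ = 0). Stage labels are independent of grade by default; a joint
table can be supplied. The default design is the 54-patient grade
composition {WD: 8, MD: 9, PD: 35, UD: 2} (108 arrays) over 2000 genes —
a desk-scale stand-in for genome-wide profiling that preserves the
mostly-null regime.

What the generator does **not** emulate: probe-level noise, batch and
spatial artifacts, heavy-tailed or gene-correlated noise,
intensity-dependent variance, and co-expression structure. Passing
recovery tests therefore demonstrates correctness of the statistics and
the selection machinery under the declared model, not performance on
real arrays.

## Problem sizes and test conditions

Calibration checks use 2000 genes × 54 balanced pairs; recovery checks
plant 40 DE genes (Δ = 1.5), 30 trend genes (step 0.5) and 10
high-vs-low signature genes (Δ = 1.2) at noise_sd 0.3 in a 2000-gene
cohort with the unbalanced 54-patient grade design, and run the
ensemble at 100 splits / 10 groups across five seeds. The synergistic
pair fixture plants two genes of effect 0.8 with anti-correlated shared
noise (each weak alone, strong jointly) among 18 nulls and checks the
exhaustive k = 2 search ranks the pair in the top 3 of 190.

## Known limitations

* The count test's Binomial(n, ½) null is a declared conservative choice,
  not a calibrated exceedance model.
* The exact trend null assumes balanced level counts (see above).
* RFE rankings on strongly redundant panels depend on C; the default is a
  general-purpose compromise.
* Multi-group accuracy is micro-averaged; per-class (macro) rates are
  recoverable from the confusion table.
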