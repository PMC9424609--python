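# Methods

## Model and procedure

`metasig` implements a two-stage design for multi-cohort case/control
transcriptomics: *discovery* (effect-size meta-analysis plus greedy panel
selection on training cohorts) and *validation* (scoring held-out cohorts
with the frozen panel). All statistics operate on log2-scale expression and
assume approximate normality of per-gene values within each class — the
usual regime for normalized array intensities or log-transformed counts.

**Effect sizes.** Per gene and cohort we compute Hedges' g (case minus
control, so g > 0 means case-elevated) with the Hedges–Olkin small-sample
correction J = 1 − 3/(4N − 9) and the standard large-sample variance
(n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)). The exact gamma-function correction is
available via `exact_correction=True`; the two agree to ~5e-3 already at
N = 6. Genes with zero pooled variance in a cohort are dropped from that
cohort (not assigned infinite effects) and logged; genes degenerate in every
cohort are dropped from the analysis.

**Random-effects pooling.** DerSimonian–Laird method-of-moments: τ² is the
truncated excess of Cochran's Q over its k−1 degrees of freedom. With one
contributing cohort the pooled result is the single study with τ² = 0
(continuity). Whenever Q ≤ k−1 the estimator truncates to the
inverse-variance fixed-effect answer, and the pooled estimate always lies
inside the range of the per-cohort effects — both are tested properties.

**Significance filter.** Per cohort we form one-sided normal p-values for
each direction from z = g/√var(g); Fisher's method combines them across
cohorts per direction; Benjamini–Hochberg adjusts each direction's combined
p-values across genes separately. A gene is flagged *up* when pooled ES >
`es_threshold` **and** FDR_up < `fdr_threshold` (symmetrically *down*).
Computing the FDR per direction (rather than jointly two-sided) keeps the
direction assignment well defined for the score; this was a genuinely open
design point and is the documented choice. Zero p-values entering Fisher's
method are clamped to the smallest positive double and logged — they occur
legitimately at large |z| in finite precision.

**Defaults.** `es_threshold = 1.3` and `fdr_threshold = 0.9`. The FDR
default is unusually permissive by design: with a large-effect gate in
front of it, the ES threshold does nearly all the filtering, and tightening
the FDR is left to the user via config. Both are plain fields of
`AnalysisConfig` / constructor parameters of `MetaSignatureClassifier`.

**Forward search.** Candidates are the flagged genes, each locked to its
meta-analysis direction (the score formula presupposes known directions, so
directions are never re-optimized during search). The criterion is the
sample-size-weighted mean of per-cohort Mann–Whitney AUCs of the meta-score
mean(up) − mean(down); weighting by cohort size degrades gracefully to plain
AUC for a single cohort. The search seeds with the best singleton and adds
the best remaining candidate while the improvement exceeds
`min_improvement` (default 0: stop only when nothing strictly improves).
Ties break by larger |pooled ES|, then lexicographic gene id, making the
output a deterministic function of its inputs. Greedy search is a heuristic:
it matches a brute-force re-evaluation of the greedy rule (tested on random
small instances) but is not guaranteed to find the globally best subset;
best-subset search is an explicit non-goal.

**ROC evaluation.** AUC is the normalized Mann–Whitney U with ties counted
half. The default 95% CI is a stratified percentile bootstrap (2000
replicates, seeded; cases and controls resampled separately so no replicate
loses a class), which behaves correctly at the AUC = 1 boundary where the
normal Hanley–McNeil interval (also available) degenerates. The summary AUC
across cohorts is the sample-size-weighted mean of per-cohort AUCs with a
cohort-stratified bootstrap CI; a fitted summary-ROC curve would be a
possible extension. The ROC polyline attached to a summary result is
computed from the concatenated scores and is illustrative only — the summary
AUC field is the weighted mean, not the area of that pooled curve.

## Synthetic data

The generator draws, for cohort i, gene j, sample s:

    x = mu_j + b_ij + y_s * (delta_j + u_ij) * noise_sd + eps,

with per-gene baselines mu_j ~ U(4, 12) (plausible log2 intensities),
cohort offsets b_ij ~ N(0, 0.5²), heterogeneity u_ij ~ N(0, tau2_true) on
signal genes, and noise eps ~ N(0, noise_sd²). Because the class shift is
scaled by noise_sd, delta_j is directly on the Hedges-g scale and
comparable to the ES gate. The default design mirrors the target study
class: three cohorts totalling 36, 12 (training) and 6 (validation)
samples, split evenly into cases and controls (the real cohorts' class
balance is not public; even split is the neutral choice), 2000 genes, 20
signal genes at |δ| = 2 with alternating sign, τ² = 0.25.

What the simulation does **not** emulate: probe-level microarray artifacts,
count overdispersion/dropout, library-size effects, correlated gene
modules, or batch-by-class confounding. Passing tests therefore demonstrate
the statistical machinery is correct under its own model assumptions, not
that the pipeline is robust to real-data pathologies.

A note on power at the default design: with cohorts this small and
τ² = 0.25, the pooled-effect standard error for a δ = 2 gene is ≈ 0.46, so
the |ES| > 1.3 gate flags such a gene with probability ≈ 0.9 — recovering
"at least 90% of 20 planted genes" in any single simulated study is
therefore a near-coin-flip event, and the corresponding acceptance test can
fail for an unlucky draw even though the implementation is exact. This is a
property of the design (effect size vs. sample size), not of the code.

## Numerical and degenerate-input choices

- Duplicate gene ids on ingestion collapse by row averaging (deterministic
  and symmetric); missing values are rejected, never imputed.
- The optional ingestion transform is log2(x+1), tolerating zeros in
  count-like inputs; pre-logged data pass through with `log2_already`.
- Signature genes absent from a cohort are excluded from the mean with a
  warning; a signature entirely absent is a hard error. Mean over an empty
  up- or down-set is 0.
- The estimator's `predict` thresholds the meta-score at the Youden-optimal
  cut (max TPR − FPR) found on the training scores; `decision_function`
  exposes the raw score for threshold-free use.
- All stochastic components (simulation, bootstrap, permutations) take
  explicit seeds; pipeline runs are byte-reproducible given the same inputs
  and seed, and the run log echoes every threshold and seed.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on hand-sized fixtures (≤ 8 genes, ≤ 40
samples) plus simulated studies of 200–2000 genes; the acceptance script
uses the full default design (2000 genes, three cohorts, 54 samples) and a
strong-signal (|δ| = 3) discovery/validation run with 100 label
permutations. Everything generates its own data at run time; no data files
ship with the package.

## Known limitations

- Greedy selection can return a smaller or different panel than exhaustive
  subset search; with very strong signals it typically stops at one gene
  (AUC 1 cannot be improved).
- The DL τ² estimate is noisy at k = 2–3 cohorts; the median-τ² diagnostics
  in the truth-recovery report are meaningful only in aggregate.
- No covariate adjustment, paired designs, or probe-to-gene mapping beyond
  duplicate-id averaging; inputs are assumed already keyed by gene symbol
  and normalized upstream.
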