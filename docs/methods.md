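# Methods

This note records the modelling choices behind `adomics`: what each stage
assumes, which knobs matter, what the synthetic generator does and does not
emulate, and the conventions adopted where the underlying procedure left a
decision open.

## Problem and data model

The pipeline predicts a binary phenotype (atopic dermatitis case vs healthy
control) from two sample-by-feature tables measured on the same cohort: a
transcriptome table of continuous, positive microarray probe intensities
(~10⁴–10⁵ features) and a microbiota table of non-negative phylum/genus
relative abundances (~10²–10³ features, mostly zeros). Sample sizes are
small relative to dimensionality, so the design centres on overfitting
control: cross-validated feature selection, noise regularization, and a
strictly held-out test set.

## Alignment and imputation

Samples with transcriptome data and a label define the cohort; its order
follows the transcriptome table. A cohort sample without a microbiota row is
retained and mean-imputed (each feature set to the mean over observed
samples), which is unbiased under the missing-completely-at-random
assumption and appropriate because the microbiota table is two orders of
magnitude narrower than the transcriptome; a sample with only microbiota
data is dropped, since imputing tens of thousands of probes from nothing is
not defensible. Imputation runs before normalization, so imputed rows
participate in each feature's min/max like any other sample.

## Splitting and normalization

`stratified_split` allocates `round(test_size · class_count / n)` test
samples per class by the largest-remainder rule, so a 161-sample cohort with
88 cases and 73 controls splits 131/30 with exactly 16 cases and 14 controls
held out, for any seed. Min-max normalization maps each feature to [0, 1];
it is the right scaler here because the chi-square score requires
non-negative input. Constant features map to 0 (the formula's denominator
vanishes; 0 preserves non-negativity). Two scopes are offered:

* `joint` (default): minima/maxima computed over training and test rows
  together, replicating the original protocol;
* `train_only`: the scaler is fitted on training rows alone and test rows
  are clipped into [0, 1] — the leakage-free variant. The no-leakage tests
  run in this mode; joint scaling leaks only feature extrema, not labels,
  but users doing honest benchmarking should prefer `train_only`.

## Chi-square feature score

The scorer is implemented directly from its matrix form (see README):
per feature, the statistic compares the class-wise sums of the feature's
mass against the expectation under label independence — a two-cell
goodness-of-fit chi-square where the "observations" are sums of continuous
normalized values rather than counts. It is a heuristic ranking score, not a
calibrated test statistic, and is used only to order features. Zero-mass
features score 0. The tests verify exact agreement (1e-10) with an
independent goodness-of-fit oracle and with scikit-learn's implementation;
the in-package version exists because this scorer is the pipeline's central
moving part and its tie-breaking (lexicographic by feature ID) must be
deterministic.

## Feature-count search and the two plans

Candidate sizes follow the geometric schedule k → max(1, ⌊0.9k⌋) from all
features down to 1 (floor chosen as the rounding rule; duplicates dropped so
the schedule is finite and strictly decreasing). Plan B runs one stratified
five-fold CV on the training set: per fold the ranking is computed on the
fold's training split only and reused across all k; the k with the best mean
validation F1 wins, ties to the smallest k (parsimony), and the final set is
the top k of the full-training ranking. Plan A nests this search inside an
outer five-fold CV and intersects the five per-fold sets; an empty
intersection falls back, loudly flagged, to features present in at least
n−1 folds. Plan B is the default, matching the original procedure's final
choice; the fixed-size mode (`n_features=35`, say) reproduces its published
set sizes directly, and `importance_floor=0.95` reproduces the
"importance ≥ 0.95 of the maximum" selection rule on max-rescaled scores
(interpreting the published importance scale, which is unit-free, as
max-rescaled).

The inner CV scores candidate sets with the same model family used for final
classification, since the two are coupled in practice.

## Models, jittering, thresholding

Model families are scikit-learn / xgboost estimators behind a uniform
spec-and-fit surface; SVMs use internally calibrated probability outputs,
seeded. Defaults are the libraries' (100 trees, C=1), all overridable —
no hyperparameter search is done beyond the feature count k and the decision
threshold, one knob at a time, under the working assumption that these
hyperparameters are weakly coupled.

Jittering adds i.i.d. Gaussian noise s ~ N(0, σ²I) with σ² = 1 to the
training transcriptome only; the microbiota block is never jittered because
its many structural zeros would be distorted by additive noise. The noise
scale notation admits two readings; the default convention is
variance = I (sd = √I), with `sd_equals_I` selectable. Noise is applied to
the raw training block before normalization (the original order; a
`post_normalization` stage is available). The published best intensity,
I = 0.001, is the default in the examples; the noise seed used in the
original experiments is tied to their data and library and is not
reproducible, so seeds here are free parameters.

Thresholding: a sample is a case iff its class-1 probability strictly
exceeds p_t. `tune_threshold` picks p_t from a grid (default 0.1…0.9) by
stratified-CV mean F1, ties resolved toward 0.5. On imbalanced data with
conservative probabilities this tends to select p_t < 0.5, trading precision
for recall.

## Evaluation

Metrics are computed from the 2×2 confusion counts by the printed formulas;
zero-denominator cases return 0 with an explicit flag instead of raising, so
degenerate CV folds cannot abort a sweep. The ROC curve is the exact step
curve of the descending-threshold sweep with (0,0)/(1,1) sentinels and one
point per tied score; AUC is its trapezoidal area, which the tests verify
equals the Mann–Whitney pairwise-ranking probability to 1e-10.

## Synthetic cohorts

The generator emulates the emulated study's shape by default: 88 cases + 73
controls, 44,608 probes, 366 taxa, one sample missing from each modality,
35 signal probes and 50 signal taxa (the published selected-set sizes).
Transcriptome intensities are per-probe log-normal (Gaussian log-mean ~
N(5, 1), log-sd ~ U(0.3, 0.8), exponentiated) so min-max normalization is
exercised on skewed positive data; signal probes shift the case log-mean by
`probe_effect` standard deviations (default d = 1.0, the effect size at
which the chi-square ranking is required to recover ≥ 90% of planted
probes). Microbiota rows are Dirichlet compositions (per-taxon gamma base
concentrations) normalized to sum to one, with signal-taxon concentrations
multiplied by `taxa_effect` (default 3.0) in cases, then cell-wise
structural zeros at probability `zero_inflation` (default 0.6, matching the
zero-heavy character of genus-level 16S tables). These distributional
choices are conventions — the original data's distributions are unpublished —
and are deliberately simple.

What the generator does **not** emulate: probe-level cross-hybridization or
probe–gene multiplicity, phylogenetic correlation among taxa, compositional
renormalization after zeroing, batch effects, and age confounding. Passing
recovery tests therefore demonstrates that the pipeline finds planted
independent signal at realistic n and p; it does not certify performance on
real cohorts, where correlation structure and confounding can only degrade
selection stability.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline at the
cohort's real sample sizes (n = 161, 131/30 split) but at reduced feature
widths — 100–2,000 probes rather than 44,608 — which exercise every code
path (the k-schedule, CV search, fusion, thresholding) while keeping the
whole suite under a minute; the package's own choice of desk-scale widths.
The recovery benchmark (20 planted probes among 1,000 at n = 160, d = 1.0,
5 seeds) is run at full stated size.

## Determinism and replay

Every stochastic stage (generator, split, folds, jitter, forests, SVM
calibration) consumes an explicit integer seed carried in its spec, and all
ranking/k/threshold ties break deterministically (lexicographic feature ID,
smaller k, closer to 0.5). A saved run log (JSON: package version + the full
resolved config) suffices to re-execute a run bit-identically via
`adomics.pipeline.replay_run`.

## Known limitations

* The chi-square score on continuous normalized data is a ranking heuristic;
  its null distribution is not chi-square distributed, so no p-values are
  exposed.
* Joint normalization (the faithful default) leaks test-set feature extrema
  into training; quantified consequence is small but nonzero — use
  `train_only` for methodological studies.
* Mean imputation ignores uncertainty and shrinks imputed samples toward the
  cohort centroid; with one imputed sample out of 161 the effect is
  negligible, but the module is not a general-purpose imputer.
* Plan A's empty-intersection fallback (majority of folds) is a pragmatic
  convention for an undefined corner case and is always flagged in results.
* No probe-to-gene annotation is shipped; an optional user-supplied
  two-column mapping can be applied downstream but identities of any
  particular cohort's selected probes are outside what synthetic data can
  reproduce.
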