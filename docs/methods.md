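# Methods

This note documents the statistical model behind `prostasig`, the conventions
that had to be fixed where more than one reasonable choice existed, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## Study design being modeled

Two independent case–control cohorts of surgically treated, clinically
localized prostate cancer: a population-based discovery cohort (278 patients
with no recurrence over long follow-up vs 27 who progressed to metastasis or
prostate-cancer death) and a nested case–control validation cohort (46 vs 32),
profiled on a bead-array expression platform (~26 000 quality-passing
transcripts after probe filtering). The scientific question is whether
individual transcripts add prognostic information *beyond Gleason score*, the
strongest routine clinical variable.

## Pipeline stages and conventions

### Preprocessing (`prostasig.ingest`)

Raw intensities are probe-filtered against an explicit keep list, quantile
normalized across samples (reference = across-sample mean of order statistics;
ties within a column receive the mean of the reference values at their tied
ranks), log2 transformed with a configurable offset, and batch adjusted.
Missing intensities are an error, never imputed. The default stage order is
filter → quantile normalize → log2 → batch adjust; each step is independently
callable.

Batch adjustment is a deliberate, exactly specified location-scale correction:
per probe and batch, subtract the batch mean, rescale residuals to the pooled
within-batch SD, restore the probe's grand mean; optional shrinkage pulls
batch means/SDs toward their across-probe average with weight n/(n+1).
Empirical-Bayes machinery (full ComBat) is intentionally out of scope — the
downstream rank-based statistics need only location/scale equalization, and
the simple form is exactly testable. Note the identifiability limit: a batch
effect constant across probes is indistinguishable from a global shift of
those samples, so the adjustment equalizes batch locations but preserves each
probe's input grand mean, including any such shift's contribution.

Replicate QC computes Pearson correlation across probes for declared blind
duplicate pairs; pairs below 0.95 are flagged (platform-typical duplicates sit
at r ≥ 0.98, which the generator-based tests reproduce).

### ROC statistics (`prostasig.roc`)

* **AUC** is the Mann–Whitney estimator (ties ½), computed as trapezoidal area
  under the tie-corrected empirical ROC (diagonal segments at tied scores);
  the two are mathematically identical.
* **pAUC** is the unnormalized integral of the same curve over FPR ∈ [0, 0.05],
  with linear interpolation at the window boundary. The unnormalized convention
  (maximum 0.05, chance 0.00125) matches the scale on which such studies print
  per-transcript pAUCs (0.002–0.02).
* **Permutation p-values** use the plus-one convention
  p = (1 + #{permuted ≥ observed})/(B+1), one-sided (*greater*) by default
  because transcripts are orientation-fixed before testing; a two-sided option
  tests distance from the chance value. p is never 0.
* **Bootstrap CIs** are percentile 2.5/97.5 intervals from class-stratified
  resampling, so every replicate keeps both classes.
* **t-tests** default to Welch (unequal variances): with group sizes as skewed
  as 278 vs 27, the pooled form is the riskier default; it remains available
  by flag.
* **BH q-values** support a total test count m larger than the p-value list,
  for panels where only a subset of tests is carried forward (the omitted
  tests are assumed less significant).

### Screening (`prostasig.screening`)

Each transcript is oriented so AUC ≥ 0.5 (orientation recorded; exact 0.5
takes +1), then ranked by AUC and pAUC descending with ties broken by matrix
row order. Rank cutoffs are floor(m·fraction), minimum 1, at default fractions
0.04 (pAUC) and 0.01 (AUC). The reduced panel is the **union** of the two
top-rank sets: with m = 26 051 the intersection could hold at most 260
transcripts, while the union spans 1042–1302 — only the union reading is
arithmetically consistent with a reduced panel of ~1216.

### Panel selection (`prostasig.selection`)

Logistic regression is fit by IRLS (relative deviance change < 1e-8, 50
iterations max, Wald statistics from observed information). The one-step-ahead
candidate fits of forward selection are batched across candidates (identical
per-candidate math, vectorized) because stability selection performs on the
order of 10⁵ such fits. Perfect separation (|logit| at the working bound) is
flagged and the candidate skipped; rank-deficient designs (e.g. a candidate
duplicating Gleason) are fit by pseudoinverse with infinite SEs on the
redundant direction, so their Wald p is 1 and the LR step statistic 0.

Gleason enters as a single ordinal covariate coded 1–4 over (≤6, 3+4, 4+3,
8–10) by default — estimable with few events — with an indicator-coding
option. Age, PSA category and stage are excluded from the base model by
default (in the motivating design they did not improve on Gleason alone); the
design matrix helper accepts them for that comparison. Model scores for the
AUC/pAUC criteria are in-sample fitted probabilities, consistent with
reporting the base model's in-sample AUC. Panels are capped at 10 transcripts
per run as a guard against degenerate long builds on resamples.

Bootstrap stability: outcome-stratified resamples (with only 27 events,
unstratified resampling frequently loses the case class), independent resample
streams per criterion, counts tallied per criterion, and robustness declared
when a transcript's count strictly exceeds `min_count` (default 40 of 1000)
for at least one criterion. `use_full_sample=True` is a diagnostic mode in
which one "resample" is the full cohort, reproducing a single deterministic
forward selection exactly.

### Validation (`prostasig.validation`)

Per robust transcript in the independent cohort: raw-scale group means, log2
difference (metastatic-lethal − nonrecurrent), fold change 2^Δ, AUC/pAUC on
discovery-oriented scores with permutation p and stratified-bootstrap CIs,
two-sided Welch t-test, BH q over the panel with m = panel size (the reading
that reproduces the published q-values of the motivating study from its
printed t-test p-values), direction concordance against the discovery
orientation, and the validated flag (any of the three p-values < 0.05 AND
q < 0.20). Combined models refit Gleason-only and Gleason+transcript on the
validation cohort; the LR statistic is the deviance difference on 1 df, and
combined AUC/pAUC are in-sample.

## Synthetic generator: what it does and does not emulate

For transcript g and sample i,

    x_gi = mu_g + delta_g·case_i + b_batch(i) + eps_gi,   eps_gi ~ N(0, sigma_g²)

with mu_g ~ U(7, 14) (log2 intensity range of expressed bead-array probes),
sigma_g ~ U(0.6, 1.1), and delta_g = 0 except for `n_planted` transcripts with
|delta| ~ U(0.3, 1.1) and sign + at rate 25/48. The residual-SD range is
derived from the arithmetic of the motivating study's printed values: effects
of 0.3–1.05 log2 units paired with per-transcript validation AUCs of 0.61–0.78
imply, via AUC = Φ(δ/(σ√2)), per-transcript SDs of roughly 0.6–1.1. Batch
offsets are N(0, 0.2) per plate (4 plates, round-robin assignment). Gleason is
drawn per sample from outcome-specific probability vectors matching the
discovery cohort's observed distribution, so Gleason is realistically
confounded with outcome — making "improvement over Gleason" a nontrivial
property — but conditionally independent of expression given outcome, because
the motivating design reports no joint model. Stage, PSA category and age are
drawn from fixed outcome-conditional distributions for report realism only.
The validation cohort reuses the truth vector (same planted transcripts and
signs) with fresh samples, mirroring the independent-cohort design.

Not emulated: within-patient correlation between tissue cores (each patient is
one sample), probe cross-hybridization, heavy-tailed or heteroskedastic
residuals, expression–Gleason correlation, censored survival structure, and
intensity-dependent batch effects. Tests passing on this generator therefore
demonstrate the pipeline's statistical machinery — calibration, recovery,
concordance — under its stated assumptions, not robustness to every artifact
of real FFPE array data.

## Numerical choices and degenerate inputs

* Tie handling is declared everywhere rather than inherited: ROC ties produce
  diagonal segments; quantile-normalization ties average the reference at tied
  ranks; ranking ties break by row order; merit ties in forward selection take
  the earliest candidate.
* Logits are clamped at ±30; weights floored at 1e-10; fitted probabilities
  clipped away from {0,1} before deviance.
* Degenerate inputs have defined behavior: single-sample quantile
  normalization warns and returns unchanged; constant-score permutation tests
  return p = 1; zero-variance-both-groups t-tests return (0, 1); a single
  bootstrap replicate yields equal CI bounds with a warning.
* Quantile normalization is exactly idempotent on tie-free data; with ties in
  some columns only, the tie-averaging perturbs the reference on a second
  pass, so idempotence is only guaranteed (and only tested) for continuous
  input.

## Calibration at small, unbalanced sample sizes

The AUC permutation p-value and the LR p-value are KS-uniform under the null
at the study's cohort sizes. The **pAUC** permutation p-value is not: at 95%
specificity with 46 controls, the ROC corner is determined by the placement of
cases among the top two or three controls, so permuted pAUC values tie exactly
and the p-value is lattice-distributed. It remains level-correct — the exact
permutation-test guarantee P(p ≤ α) ≤ α holds, measured at 0.053 for α = 0.05
over 1000 null runs — and becomes KS-uniform at larger balanced sizes
(n = 150/150). The test suite asserts exactly these properties.

## Problem sizes used in tests

The test and acceptance runs use the package's documented desk scale: 2000
transcripts with 20 planted effects for end-to-end recovery (full cohort
sizes 278/27 and 46/32), 200 stability panels with the robustness threshold
scaled proportionally (8 of 200, matching 40 of 1000), 199–1000 permutations
and 500–2000 bootstrap replicates, and 200-replicate calibration/coverage
simulations. Full-scale runs (26 051 transcripts, 1000 panels, 10 000
permutations) use the same code paths through the same configuration objects.

## Known limitations

* In-sample AUC/pAUC for model comparison is optimistic; the package reports
  it because that is the convention being implemented, not because it is the
  best estimate of out-of-sample performance.
* Forward selection with strongly correlated candidates keeps only
  first-entering transcripts per resample; stability counts, not the single
  ordered panel, are the interpretable output.
* The robust-marker threshold (> 40 of 1000) is a stability heuristic, not an
  error-rate guarantee; the null false-selection behavior is characterized by
  simulation in the tests.
* No probe-to-gene collapsing, survival modeling, multi-transcript scoring, or
  pathway analysis; these are explicit non-goals.
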