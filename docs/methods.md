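# Methods

This note documents the statistical procedures implemented in `seromir`,
the defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical conventions that matter when comparing
results against other implementations.

## Synthetic cohorts

`cohort.generate_cohort` draws a case/control serum-miRNA cohort whose
default configuration mirrors the structure of a large public AD serum
microarray cohort:

* **Group sizes** 1021 AD / 288 controls.
* **Age** truncated normal per group on [55, 95] years; AD location 80,
  scale 5.9; control location 71, scale 6.7. Locations are the published
  group medians; scales are IQR/1.349 from the published interquartile
  ranges. Only medians and IQRs are published, so location/scale remain
  free configuration with these defaults.
* **Sex** Bernoulli(female) with the published group proportions
  (AD 714/1021, control 137/288).
* **APOE ε4 count** categorical over {0, 1, 2} with the published group
  frequencies (AD 577/376/68, control 238/46/4).
* **Features** 2,500 miRNAs: 20 positively and 12 negatively
  MMSE-correlated candidates (the literature-derived sets after family/arm
  expansion) plus simulated background probes. Mean log2 intensities are
  uniform on [6, 14].
* **Group effects** enter as exact mean shifts on the log2 scale (the
  configured log2FC, AD minus control) before noise. Defaults are −0.3 for
  the positive set and +0.3 for the negative set — modest shifts consistent
  with the expected directions (positively correlated miRNAs down in AD)
  and with serum effect sizes small enough that single candidates are weak
  classifiers while the sets are clearly detectable at the default n.
* **Correlation clusters** members of a cluster share one Gaussian latent
  factor. For a Spearman target ρ_s the Pearson loading is set analytically
  via the Gaussian rank-correlation map, r = 2·sin(πρ_s/6), so the realized
  Spearman approaches the target. The default plants the 18-member cluster
  observed at |ρ| ≥ 0.80 in the empirical network, at ρ_s = 0.85.
* **Noise** named features (candidates, cluster members, any feature with a
  configured effect) have residual SD `noise_sd` (default 1.0 log2 units).
  Background probes draw their SD uniformly from `background_sd_range`
  (default 0.4–1.6): real arrays contain probes from near the noise floor
  to highly variable, and without that spread a row-SD quantile filter
  would remove a uniformly random quarter of features rather than the flat
  ones.
* **Missingness** MCAR at `missing_rate` (default 0) to exercise
  pairwise-complete and imputation code paths.

Confounding of age/sex/APOE with diagnosis arises purely from the per-group
sampling parameters — an observational imbalance, not a structural causal
model. The generator therefore supports testing covariate *adjustment*
(does the machinery remove an association that is explained by the
covariates) but says nothing about causal identifiability. Other realism
gaps: no batch structure, no probe-level effects, no intensity-dependent
missingness, Gaussian noise only, and candidate effect sizes that are
homogeneous within a set. Tests passing on these cohorts demonstrate that
the machinery is correct and calibrated under its stated model, not that
the pipeline's operating characteristics transfer to any particular real
dataset.

## Normalization and filtering

Raw intensities are log2-transformed (strictly positive input required)
and quantile-normalized across samples: each sample's sorted vector is
replaced by the across-sample mean of sorted vectors. Ties within a sample
all receive the mean of their tied positions' target values, which makes
the transform idempotent up to floating point. Samples with missing cells
are mapped through interpolation of the reference distribution at their
observed quantiles; missing cells stay missing.

Low-variability features are removed by row standard deviation: features
with SD below the q-quantile (default q = 0.25) of all row SDs are dropped.
The quantile uses the linear-interpolation order-statistic definition (the
numpy default); no convention is published for this step. Filtering is done
on the normalized matrix before model fitting; whether the original
analysis filtered before or after sample weighting is not stated.

## Moderated differential expression

Per feature, ordinary least squares of log2 expression on
`[intercept, diagnosis(AD=1), covariates]`. APOE ε4 can enter as a 0/1/2
count ("continuous", the default), as two dummies ("categorical"), or be
excluded; sex is coded female = 1. Missing expression values are handled
complete-case within feature; features with fewer than 10 complete samples
in either group are dropped with a warning. An optional positive per-sample
weight vector turns the fit into WLS (uniform by default); data-driven
array-quality weights are deliberately out of scope.

The residual variances s²_g on d_g df are modeled as scaled-F draws around
a prior s₀² with d₀ prior df. Writing
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the prior is estimated by moments:
the excess of Var(e) over mean trigamma(d_g/2) equals trigamma(d₀/2)
(solved by Newton inversion of the trigamma function), and s₀² follows from
the mean of e. With `trend=True` (default) the location of e is a lowess
fit (span 0.5) on average log2 intensity, giving an intensity-dependent
prior variance; d₀ is then estimated from the residuals around the trend.
This matches the standard non-robust empirical-Bayes moderated-t
construction; on a shared fixture the estimated (d₀, s₀²) and all moderated
t and p-values agree with the reference R implementation (limma, non-robust,
no trend) to ~1e-8 relative — that agreement is asserted in the test suite
via an Rscript oracle. The `robust` flag is reserved and warns that robust
hyperparameter estimation is not implemented. Setting `prior_df=0` disables
moderation and reproduces ordinary per-feature t-statistics exactly.

Moderated t uses s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) on d₀ + d_g df;
two-sided p; BH q-values via the step-up formula with input order
preserved. Covariate-model sensitivity is summarized by the Jaccard index
of the q < α significant sets (reported missing, not zero, when both sets
are empty) and the Spearman correlation of log2FC over shared features.

## Directionality statistics and signature score

Expected signs: positive-set members (positively correlated with MMSE)
should be down in AD (log2FC < 0); negative-set members up. A member is
*consistent* iff q < 0.05 and the sign matches. The set-level mean-rank
test ranks the chosen statistic (moderated t preferred, log2FC as
fallback) over **all retained features** — the post-filter universe — and
compares the set's rank sum to its permutation null with the normal
approximation and tie-corrected variance, one-sided in the expected
direction. No continuity correction is applied, so the two one-sided
p-values sum to exactly 1 in the absence of ties; the approximation tracks
exhaustive subset enumeration (mid-p convention) within 0.02 for n ≤ 10
provided min(|set|, |complement|) ≥ 3 — below that the rank-sum lattice is
too coarse for any normal approximation, which is why the enumeration
check is scoped to that regime. Sign tests drop exact zeros and use the
exact binomial tail; signed-rank tests are exact for n ≤ 25 and use the
continuity-corrected normal approximation beyond.

The signature score z-scores each usable candidate feature across **all
samples** (not within diagnosis groups — scores must be computable for a
new sample without label knowledge) and averages with weight +1 for the
negative set and −1 for the positive set; zero-SD or absent features are
skipped with a warning, missing cells are ignored per sample. The score is
invariant to per-feature affine rescaling and member order. Its group
association is an OLS of score on diagnosis + age + sex + APOE ε4 count.

## Covariate diagnostics and partial rank correlations

Operating-point metrics come from raw confusion counts with
zero-denominator metrics reported missing. Youden thresholds maximize
J = sensitivity + specificity − 1 over midpoints between adjacent distinct
scores plus ±∞, the classification rule being score ≥ threshold ⇒ positive
(the direction consistent with the published integer thresholds; for sex
the published "threshold 1 (female)" is reproduced by coding female = 1,
male = 0). Ties in J break toward the lowest threshold. Cross-validated
transfer uses stratified 5-fold CV: a univariate logistic model and its
training-fold Youden threshold are applied unchanged to the validation
fold; fold metrics are summarized as mean ± SD. AUC is the tie-aware
pairwise concordance; AP the rank-based step sum without interpolation.
Cramér's V uses the Pearson chi-square without continuity correction,
V = sqrt(χ²/(n·min(r−1, c−1))).

miRNA-covariate associations are partial Spearman correlations by rank
residualization: all variables rank-transformed (ties averaged), feature
and target OLS-residualized on the adjusters plus intercept, Pearson
correlation of residuals, p from the t approximation on n − 2 − k df, BH
across features. With no adjusters this reduces exactly to Spearman's ρ
(rank point-biserial for a binary target).

## Correlation network and clusters

Feature-feature Spearman correlations use pairwise-complete observations;
entries with fewer than `min_pairs` (default 10) complete pairs are
missing, and missing entries contribute no edge (conservative
connectivity). Clusters are connected components of the |ρ| ≥ threshold
graph; singletons are retained as size-1 clusters, cluster IDs are the
lexicographically smallest member (order-invariant), and the threshold
scan reports clusters of size ≥ 2, maximum size and singleton count per
threshold (descending grid, default 0.90–0.70; primary analysis at 0.80).
The module eigengene is PC1 of the z-scored member block (members
median-imputed first), scaled to unit variance, sign oriented so the mean
member loading is positive; variance explained is λ₁/Σλ.

## Panel selection

`SelectionConfig` defaults: 5 outer folds × 4 repeats (= 20 run units,
matching the published run count; the decomposition into 5 × 4 is this
package's choice and both knobs are configurable), 5 inner folds, gain
gates ΔAUC ≥ 0.005 (cross-cluster) and ≥ 0.010 (within-cluster). During
the greedy loop the inner-CV AUC uses the elastic-net pipeline at a fixed
penalty (strength 0.1, l1_ratio 0.5) — no hyperparameter search inside the
selection loop, to keep it tractable; full tuning happens in final
evaluation. Tie-breaking is higher gain → higher univariate CV-AUC →
lexicographic ID throughout, which makes runs deterministic at fixed seed.

The one-representative-per-cluster rule admits a second member from an
already-used cluster only through the stricter gate, *in addition to* the
first member; whether the original procedure adds or replaces is ambiguous,
so `within_cluster_mode="replace"` is available as the alternative reading.

Frequency aggregation deduplicates within each outer-fold × repeat run
unit, sums counts across units, then keeps the highest-frequency member
per cluster (ties by univariate CV-AUC, then ID). The K-AUC path evaluates
baseline + top-K panels by stratified CV, and the 1-SE rule picks the
smallest K with AUC ≥ best AUC − SE(best K), SE = fold SD/√folds. The
max-minus-one-SE construction is inferred from the two published
threshold/AUC pairs (0.823→0.810 and 0.836→0.823, both consistent with
SE ≈ 0.013); `select_k_one_se` also accepts an explicit SE. The published
K-AUC path for the age+sex baseline applies the rule to the standard
incremental path only; the alternative K=2 sensitivity panel is not part
of that path.

## Classifier evaluation

The primary classifier is elastic-net logistic regression (saga solver);
penalty `strength·[l1_ratio·L1 + (1−l1_ratio)/2·L2]` with strength = 1/C.
The tuning grid — strength ∈ {0.001, 0.01, 0.1, 1, 10} × l1_ratio ∈
{0.1, 0.5, 0.9} — is this package's default; none is published. Median
imputation and standardization live inside the training pipeline so no
test-fold statistics leak. Class imbalance is handled by inverse-frequency
class weights (on by default) with an optional explicit per-sample weight
vector (which bypasses the grid search, since per-sample weights are not
routed through it). Comparators (linear/RBF SVM, random forest, gradient
boosting) sit behind the same interface with small default grids.

Nested CV is stratified 5 × 5, single-threaded, seeded. With repeats,
out-of-fold probabilities are averaged across repeats *before* pooled
metrics (the alternative — averaging per-repeat metrics — is not used).
Pooled OOF probabilities give AUC (95% CI by 2,000 class-stratified
bootstrap resamples, percentile interval), average precision and the Brier
score. ECE uses 10 equal-width bins — stated prominently because ECE is
bin-sensitive: Σ (n_b/n)·|mean prob − observed rate| over non-empty bins.
Decision curves evaluate NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t) on the grid
p_t = 0.01…0.50 (step 0.01) against treat-all and treat-none. Operating
points report the Youden optimum and the constrained points (highest
sensitivity at specificity ≥ 0.90 and vice versa), rule prob ≥ threshold ⇒
AD, constraints evaluated on the OOF set itself; unattainable constraints
yield missing metrics with a warning.

The absolute published model metrics (AUC ≈ 0.84 for the best composite
model, etc.) require the original cohort's individual-level data and are
not reproduction targets; the evaluation machinery is instead validated by
permutation-null calibration (OOF AUC 0.5 ± 0.05), separable-case
behavior, the constant-predictor Brier identity p(1−p), and the
decision-curve closed forms.

## Pipeline determinism

`run_pipeline` executes synthesize → preprocess → de → direction →
covariates → network → select → evaluate, any stage skippable. Per-stage
seeds are derived by SHA-256 hashing of (top-level seed, stage name) —
stages cannot couple through shared RNG state — and the manifest records a
digest of the canonical config, so identical configs produce byte-identical
outputs (asserted file-by-file in the test suite).

## Problem sizes in tests

The test and acceptance workloads use reduced problem sizes chosen to keep
each property's Monte-Carlo error well inside its assertion band: effect
recovery at n = 300/300 over 20 seeds, type-I calibration on 200 seeds of a
50-feature 100 vs 100 null (10,000 p-values), permutation nulls with 50
permutations of a 120-sample 5-feature set, panel recovery over 20 seeds of
a 300-sample 10-feature cohort with one planted signal and a ρ = 0.9 decoy
cluster, and cluster recovery at n = 500. Full-scale defaults (1021/288,
2,500 features) run in the worked example and the `seromir run` pipeline.

## Known limitations

* Robust empirical-Bayes hyperparameter estimation and data-driven array
  weights are not implemented (flag reserved / user-supplied weights only).
* The mean-rank set test is asymptotic; for sets or complements smaller
  than 3 its tail probabilities deviate from the exact enumeration by more
  than 0.02 at small n (use the sign/signed-rank tests there).
* Partial rank correlation p-values use the t approximation, adequate at
  the n ≥ 10 precondition but approximate under heavy ties.
* The elastic-net coefficient split across strongly collinear features is
  not identified at l1_ratio = 1 (only the sum is); interpret panel
  coefficients at the cluster level.
* Decision-curve net benefit is evaluated at the cohort prevalence; in
  screening populations with lower prevalence the treat-all reference and
  absolute net benefits shift, though model rankings are typically stable.
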