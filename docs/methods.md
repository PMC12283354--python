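# Methods

`micromet` re-implements, as a tested pipeline over synthetic cohorts, the
analysis chain used in microbiome–metabolome integration studies of impaired
glucose control: per-metabolite explained-variance (EV) attribution to
clinical, microbiome and diet feature groups with gradient-boosted decision
trees (GBDT); Shapley-value bi-networks with keystone ranking; bidirectional
covariate-adjusted mediation; glucose-status metabolite signatures; and
random-forest / ridge classification benchmarks. Real cohorts of this kind
are controlled-access, so a first-class synthetic-data generator plants
known structure and every statistical claim in the test suite is a
parameter-recovery or calibration statement against that planted truth.

## Synthetic cohorts

`synthgen.gen_feature_bundle` draws the three design matrices over one
sample index:

- **Microbiome** (relative abundances of metagenomic species, MGS):
  correlated Gaussians with a rank-5 loading structure and heterogeneous
  per-taxon location, exponentiated to log-normal marginals, multiplicative
  zero-inflation (default 30% of cells) applied *before* closure to the
  simplex. The most abundant taxon of each sample is never zeroed, so rows
  remain valid compositions. This reproduces the compositionality, sparsity
  and heavy right tail of real MGS tables; it does not model phylogenetic
  structure or sequencing depth.
- **Clinical**: age ~ U(50, 64) years, sex ~ Bernoulli(½), BMI ~ N(27, 4²)
  kg/m² (clipped to a plausible range), plus correlated continuous
  laboratory covariates.
- **Diet**: ordinal food-frequency codes 0–8 obtained by thresholding a
  correlated latent Gaussian at column-specific cut points, with
  missing-completely-at-random cells (default 5%). The ordinal-code choice
  is a stand-in for questionnaire-derived frequency conversions, not an
  inference about any particular instrument.

**Metabolites.** Each metabolite is `y = Σ_g s_g(X_g) + ε` with each group
component rescaled so `Var(s_g)/Var(y)` equals the requested signal
fraction (fractions must sum to ≤ 0.95, leaving irreducible noise). `s_g`
is a sparse linear form over `n_active` standardized features (default 5),
optionally plus variance-normalized pairwise products so trees have
structure that a linear fit cannot express. The generating predictor —
active indices, weights and the standardization constants of the generating
cohort — is frozen into a ground-truth JSON sidecar, so tests can evaluate
the *oracle* R² on fresh draws. The sidecar is never read by analysis
stages.

**Labels and shifts.** Glucose-status groups NGT/IFG/IGT/CGI/T2D are
multinomial with proportions 220/185/173/74/45 out of 697, matching a
typical discovery cohort; planted differential metabolites are shifted
additively on the standardized scale in the stated groups.

**Mediation triplets.** `mediator = a·MGS1 + γᵀz + ε₁`,
`MGS2 = c′·MGS1 + b·mediator + γᵀz + ε₂` with covariates z = (age, sex,
BMI). The analytic proportion mediated is `a·b/(a·b + c′)`, flagged
undefined (not raised) when the total effect vanishes.

## Metabolite preprocessing

Metabolites measured in fewer than 10 samples are removed; remaining values
are log10-transformed; missing cells are imputed with the per-metabolite
minimum (missingness on semi-quantitative platforms is predominantly
left-censoring at the detection limit); each column is standardized with
the sample (n−1) SD. Constant columns after imputation are dropped with a
warning rather than divided by zero. Standardization is applied within each
input table. Microbiome predictors enter models as log10(abundance + 1e-6);
diet columns missing in > 80% of samples are excluded and remaining missing
diet cells are imputed with the column mode. Shannon diversity is
`H = −Σ p_i ln p_i` in nats.

## Explained variance and its inference

For one metabolite and one feature group, EV is the out-of-sample
coefficient of determination `R² = 1 − SSE/SST` of pooled out-of-fold
predictions from k-fold CV (k = 5), computed on predicted-vs-measured
values; it may be negative, and negative values are genuine (a model worse
than the mean). Within each training fold, hyperparameters are chosen by a
10-draw random search on an inner 75/25 split (depth 3–8, leaves 8–64,
learning rate 0.01–0.2 log-uniform, feature subsampling 0.5–1.0); the best
draw is refit on the whole training fold. `oof_predict(..., n_repeats)`
optionally averages out-of-fold predictions over repeated fold splits,
which shrinks the model-variance penalty of the downstream R²; the
recovery experiments use 3 repeats.

Two resampling devices give the inference:

- **Bootstrap CI** (B iterations, default 1000): whole samples are
  resampled with replacement and the CV is re-run on each resample; the 95%
  CI is the 2.5/97.5 percentile of the bootstrap R² distribution. CV folds
  inside a resample partition the *unique* original sample ids, so a
  duplicated sample never appears in a training and a test fold
  simultaneously. This matters: with naive row-wise folds the duplicate
  leakage shifts the bootstrap distribution upward by ≈ 0.3 R² units under
  the null, and the CI then essentially never brackets the point estimate.
- **Wald test against a permutation null** (M = 10 permutations): the same
  CV pipeline is run on label-permuted data, and the z-ratio
  `(R²_point − mean_perm)/(sd_perm·√(1+1/M))` is referred to a t
  distribution with M−1 degrees of freedom (two-sided). The centring is
  necessary because out-of-sample R² has a strictly negative expectation
  under independence (the model's prediction variance is pure loss), so the
  naive ratio `R²/SD` is not a pivot: measured on null data (n = 200,
  p = 20) it rejects either ~33% or ~0% of the time at α = 0.05 depending
  on the model configuration. The t reference is exact for the studentized
  difference of iid normal statistics — under the null the point statistic
  and the M permutation statistics are exchangeable — and leaves only the
  skewness of the R² statistic as an approximation error (measured type-I
  error ≈ 0.05–0.08 at α = 0.05).

Large resampling simulations use a fixed weak configuration (4 leaves,
depth 3, learning rate 0.25, 12 boosting rounds, 15 histogram bins) instead
of the random search; under the null the search only selects ever-weaker
models while multiplying cost tenfold.

**q-values.** Storey q-values with the smoother π₀ estimate: π₀(λ) over
λ = 0.05…0.95 smoothed by a cubic spline and evaluated at λ = 0.95; when
the estimate leaves (0, 1] — or fewer than 100 P values are available — the
computation falls back to π₀ = 1, where q-values coincide exactly with
Benjamini–Hochberg. The significance gate is q < 0.1 throughout.

**Relative predictive power.** Principal components of the preprocessed
metabolite matrix (smallest count explaining ≥ 80% of variance, capped at
20) are each predicted from every group and from all features; a group's
share is the eigenvalue-weighted mean of max(EV, 0) over components divided
by the full model's, normalized over the three groups. Negative
per-component EVs are floored at zero before aggregation since negative
out-of-sample R² carries no attributable variance. When the full model's
weighted EV is below 1e-3 the shares are flagged uninformative rather than
divided by a near-zero denominator.

**Cross-cohort replication.** EV pairs from two cohorts enter an OLS of B
on A; points with Cook's distance above 3× the mean Cook's distance are
flagged influential outliers; an exact fit yields all-zero distances by
convention.

## Shapley attribution and the bi-network

Per-sample, per-feature attributions come from the exact path-dependent
TreeSHAP algorithm (LightGBM's native `pred_contrib`), which satisfies
local accuracy: base value plus the attributions of a sample reproduce that
sample's prediction to machine precision. The test suite checks this bound
(1e-6) on every fitted model and additionally verifies two-feature models
against a brute-force Shapley oracle that enumerates feature coalitions
with cover-weighted conditional expectations.

Per metabolite model, a feature's importance is the mean |φ| across samples
with the sign of the mean φ (for comparison against linear-model
coefficients the direction is instead taken from the φ–feature correlation,
since attributions average to ≈ 0 by construction). Scores for MGS features
are pooled across all metabolite models; the K = 300 largest pairs (ties
broken lexicographically for determinism) form a strictly bipartite
MGS–metabolite graph. Keystone candidates are ranked by degree and by
shortest-path betweenness (computed within components; both raw pair counts
and the (N−1)(N−2)/2-normalized variant are emitted). Force-directed
layouts are export-only.

## Mediation

Two OLS fits per direction — `mediator ~ exposure + age + BMI + sex` and
`outcome ~ exposure + mediator + age + BMI + sex` — give the
product-of-coefficients estimator: ACME = a·b, ADE = c′, total = ACME + ADE
(an exact identity for linear no-interaction models, where the product
coincides with the counterfactual indirect effect). The proportion mediated
is ACME/total, flagged undefined when |total| < 1e-8. Inference is a
nonparametric pairs bootstrap (resample rows, refit both models; default
B = 1000): percentile CIs for ACME and the proportion, and a P value equal
to twice the smaller tail of the bootstrap ACME distribution around zero,
capped at 1. Variables are standardized before fitting (the proportion is
scale-invariant; this only stabilizes numerics); `standardize=False`
centres only, keeping coefficients on the structural scale for
parameter-recovery checks. Bidirectional analysis runs both orientations
and reports them side by side. Proportions are reported raw, without
truncation to [0, 1].

## Signatures

Differential calling per subgroup contrast uses two-sided Wilcoxon rank-sum
tests: exact enumeration when the pooled sample is tie-free with n ≤ 25,
otherwise the midrank normal approximation with tie-corrected variance and
continuity correction. Direction is the sign of the median difference. A
metabolite is a *consistent* signature when q < 0.1 with the same direction
in both the discovery and validation inputs. Odds ratios per SD of
metabolite come from maximum-likelihood logistic regression adjusted for
age and sex, with Wald CIs; perfect separation is flagged and the CI
reported unbounded. Overlap summaries count exact intersection regions;
proportion comparisons use Pearson chi-squared without continuity
correction; longitudinal responses use within-subject one-way ANOVA
(F = MS_time/MS_error after removing subject effects, df = (t−1),
(t−1)(s−1), complete-case with a warning). Response clustering is
agglomerative Ward on Euclidean distances over signed significance codes,
cut at k = 8 (reduced with a warning when fewer distinct rows exist); rows
are pre-sorted lexicographically so labels are invariant to input order.

## Classification

The random-forest protocol: stratified k-fold CV repeated r times (defaults
10×10; drivers use 5×2 with 150–500 trees to stay within desk-scale
budgets, the tree count default remains 5000); the minority class is
upsampled with replacement *inside each training fold only*; a small
hyperparameter grid is scored by Cohen's kappa at a 0.5 posterior cut and
the winner's per-fold AUC (Mann–Whitney formulation, ties ½) is recorded;
the winning configuration is refit on all data. Regression uses per-fold
`1 − SSE/SST` averaged over folds. Ridge regression penalizes features but
not covariates (block-penalized normal equations), with the penalty chosen
from 100 log-spaced values spanning six orders of magnitude by 10-fold CV
squared error.

## Pipeline and determinism

`pipeline.run_pipeline` chains simulate → preprocess → ev → attribute →
network → mediate → signatures → classify → report from one validated
configuration; every stage writes plain TSV/JSON, and the manifest records
per-stage seeds (derived by hashing the master seed with the stage name),
SHA-256 digests and timings. Reruns skip stages whose configuration
signature and output digests still match. All stages are deterministic
given the seed: LightGBM runs single-threaded with fixed seeds, and ties in
top-K selection are broken lexicographically. The demo configuration
(n = 300 samples, 40 metabolites, 60 MGSs, 8 clinical and 15 diet
variables, B = 100, M = 5 permutations, the fast model configuration) runs
in ≈ 4.5 minutes on one CPU.

## Validation battery and problem sizes

The experiments module fixes the sizes used by the drivers, tests and the
acceptance script (chosen so the full battery is a desk-scale computation):

- Null calibration: n = 200, p = 20, B = 100, 200 replicates; rejection
  rate at α = 0.05 must sit in [0.02, 0.10], and the bootstrap CI must
  bracket the point estimate in ≥ 95% of replicates.
- Planted-EV recovery: fraction 0.4 on the microbiome group, n = 1000,
  p = 50, ten cohorts, 3-repeat CV with the full search; the median
  estimate must land within ±0.08. Note the estimand itself fluctuates:
  the oracle predictor's realized R² has an SD of ≈ 0.03 across cohorts of
  this size, and tree models sit ≈ 0.05 below the oracle on sparse linear
  signals.
- Relative power: planted 0.4/0.2/0.1 shares; ordering recovered in ≥ 90%
  of 20 seeds.
- Mediation: (a, b, c′) = (0.5, 0.5, 0.25) gives proportion 0.5; the point
  estimate at n = 5000 must be within ±0.05 and the 95% ACME CI must cover
  the truth in 90–99% of 200 simulations at n = 500, B = 200.
- Classifiers: a two-feature +2 SD shift at n = 300 must reach CV AUC
  ≥ 0.9; label-permuted data must average 0.5 ± 0.05 over 20 seeds.
- Oracles: rank-sum exact P vs full enumeration for all tie-free group
  sizes up to 5×5; betweenness/degree vs brute-force path enumeration on
  100 random graphs of ≤ 7 nodes; chi-squared, AUC and the 2×2 logistic OR
  against closed forms; the preprocessing chain against a hand-computed
  toy.

What passing these does *not* show: the generator draws groups
independently (no diet→microbiome causality), plants additive signals, and
omits batch effects, compositional spurious correlation from shared
denominators, and longitudinal kinetics — so recovery here bounds
best-case, not field, performance of the methods on real cohorts.

## Known limitations

- The permutation-centred Wald test is mildly anticonservative by
  construction (t₉-tailed); raising M tightens it at linear cost.
- Bootstrap CIs for EV inherit the slight pessimism of resamples containing
  ≈ 0.632 unique samples.
- The GBDT EV estimator is downward-biased on sparse linear signals
  (≈ −0.05 at n = 1000); the bias shrinks with n and with repeats but is
  not corrected.
- Ridge covariate adjustment assumes covariates of full rank; no
  quasi-separation handling beyond flagging in the logistic OR.
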