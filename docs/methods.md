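# Methods

This note documents the models implemented in `smallarea`, the choices made
where the method leaves room, and what the synthetic-data results do and do
not show about real data.

## Problem setting

A custodian must decide, before releasing person-level health data with a
geographic code, which areas are *too small*. The operative risk measure is
**population uniqueness**: the fraction of an area's residents who are the
only person in that area with their exact combination of quasi-identifier
values. Three thresholds are supported — 0% (any unique), 5% and 20% — with
stricter thresholds appropriate for less-trusted recipients.

## Quasi-identifier models and MaxCombs

A scheme declares categorical quasi-identifiers with fixed response-category
counts; counts are declared, not inferred from data, because the category
design (5-year age bands, $15K income bands, ...) is a releasing decision,
not a data property. The default scheme contains 11 census variables:
gender (2), age (24), language (4), ethnic origin (26), religion (3),
visible minority (4), schooling (9), marital status (5), income (22),
aboriginal identity (8), activity difficulties (4). The four
ethnicity-related variables act as variants of one generic ethnicity slot,
giving 8 distinct qids.

A model is any 2–5 member subset containing at least one high-utility
variable (age or gender); remaining members are sensitive. The pure
{age, gender} pair is a valid model. Each subset containing the generic
ethnicity slot is expanded into one concrete model per variant. This yields
358 models — 90 containing both age and gender (42 before variant
expansion), 134 with age only (56 before expansion), 134 with gender only —
with MaxCombs (the product of member category counts) ranging from 6
(gender × religion) upward. Enumeration output is sorted by model size then
member names so downstream artifacts are reproducible. For schemes other
than the default structure, the enumeration takes explicit size bounds; the
composition rule (≥ 1 high-utility member) is applied as declared by the
scheme's utility classes.

## Estimating population uniqueness from a sample

Given an area's sample spectrum `f_j` (classes of size `j`), sampling
fraction `p` and population `N`:

- **Naive spectrum estimate.** `P̂(F=j) = f_j / Σ_k f_k` estimates the
  population class-size distribution from the sample class-size
  distribution.
- **Subsampling model.** Under binomial subsampling a population class of
  size `j` appears as a sample singleton with probability
  `j·p·(1−p)^{j−1}`. Binomial rather than hypergeometric is the default —
  at the area sizes of interest (hundreds to tens of thousands) the two are
  indistinguishable, and the binomial form is closed-form; an exact
  hypergeometric option (`subsampling="hypergeometric"`) is provided.
- **Bayes step and scaling.** `P̂(F=1|f=1)` converts sample uniques to
  expected true uniques among them; dividing by the per-class detection
  probability `P(f=1|F=1) = p` scales the count to the population. The
  result is divided by `N` and clipped to [0, 1]; the clip matters only in
  small, highly unique areas where the scaled count can exceed `N`.

The estimator is exact at `p = 1` (reduces to sample uniqueness) and is
known to overestimate at small `p`; at the 20% design fraction the bias is
modest. On the generator's reference regime (30 areas of 1,000–20,000
people, Zipf(1.2) marginals, `p = 0.2`) the mean absolute error against the
exact-count ground truth is ≈ 0.06 with Spearman rank correlation ≈ 0.96;
the error is almost entirely upward bias, i.e. conservative for disclosure
control.

Missing quasi-identifier values form their own category, which preserves
distinguishability and is therefore conservative as well.

Two closed-form screens accompany the estimator: the drawer-principle flag
(`N ≤ k` means a unique is guaranteed possible) and the uniform-allocation
expectation `1 − (1 − 1/k)^{N−1}` for the fraction of individuals sharing a
class, which quantifies how much the drawer-principle flag overstates risk
(for `N = 15`, `k = 48` about 26% of individuals would be non-unique).

## Threshold indicators and the risk model

Indicators are strict: `I05 = [û > 0.05]`, `I20 = [û > 0.20]`, so an
estimate of exactly 5% is not above the threshold. The risk model is a
logit in the area population `POP` and the model's `MaxCombs`, with their
interaction; predictors are centered (to decorrelate the interaction from
the main effects) and scaled by 10,000 (to keep the interaction's magnitude
computable). Centering constants are always computed from the training data
and serialized with the model; a model file without a scaler refuses to
predict rather than silently assume centers. The flagging cutoff is
`π > 0.5` (strict), overridable per call.

### Unbalanced-data corrections

Above-threshold observations are the minority. Two corrections are
implemented:

- **Down-sampling with prior correction.** Keep the minority class, draw an
  equal-size simple random subsample of the majority (seeded, without
  replacement), fit by maximum likelihood, then subtract
  `ln[((1−τ)/τ)·(ȳ/(1−ȳ))]` from the intercept, where `τ` is the full-data
  prevalence and `ȳ` the balanced-sample prevalence. Slopes are unaffected;
  the correction restores the original prevalence scale exactly.
- **King–Zeng.** Fit on the full data, then subtract the small-sample bias
  `(XᵀWX)⁻¹XᵀWξ`, with `W = diag(π̂ᵢ(1−π̂ᵢ))`, `Q = X(XᵀWX)⁻¹Xᵀ` and
  `ξᵢ = ½·Qᵢᵢ·(2π̂ᵢ−1)`. Only the diagonal of `Q` is formed, so the
  correction is O(n·p²).

Both recover generator-true coefficients within their 95% confidence
intervals at n = 50,000, and the King–Zeng correction reduces coefficient
RMSE relative to the uncorrected fit when positives are rare (~harder
regimes with a few hundred positives in 5,000 rows).

(Quasi-)separation — common on strong-signal synthetic tables — drives the
MLE toward infinity and makes the Newton step's Hessian singular. The fit
then falls back to BFGS and the model carries a warning status instead of
failing: saturated probabilities still rank and flag observations
correctly, which is all the downstream pipeline uses.

### Influential observations

A single-pass dfbetas screen: fit a preliminary model, drop rows whose
largest absolute standardized coefficient change exceeds `2/√n`, refuse to
proceed if that would empty a class. On clean synthetic data the removal
rate lands in the low single-digit percent range, consistent with what a
well-specified model should discard.

### Published coefficients

The shipped 5% model (779.1, −37.35, 137.8, −6.5) and 20% model (63.3, −6,
11.8, −1) are ready-to-use decision rules fitted on 2001 Canadian census
data by down-sampling. Their centering constants are unrecoverable, so
prediction requires attaching a `CenteredScaler`; constructing a published
model without one emits a warning and any prediction raises. Within their
intended range the 5% model's logit is strictly decreasing in population at
centred MaxCombs (b₁ < 0): larger areas are lower risk.

## Evaluation

Stratified 10-fold cross-validation (stratification is a deliberate
strengthening of plain decile splits: with rare positives an unstratified
fold can contain no positive at all). The rebalancing correction and the
scaler are recomputed inside each training split. Predictions are pooled
across folds — each observation predicted exactly once — into one confusion
matrix at the 0.5 cutoff; AUC is the Mann–Whitney rank statistic with
midrank tie handling, which equals the probability a random above-threshold
observation outranks a random below-threshold one. Runs are bit-reproducible
under a fixed seed.

## Synthetic census generator

The generator emulates the *structure* of urban-FSA census microdata: area
populations drawn log-uniformly in [200, 78,457] (the population range of
the areas the models target), categorical values drawn per declared scheme,
and a per-area 20% simple random sample without replacement. Defaults:

- **Zipf(1.2) category marginals.** Real census categories are heavily
  skewed (a few large language/ethnicity groups, a long tail); skewed
  marginals produce realistic within-area class structure and the
  unbalanced indicator regime the corrections exist for. Uniform and
  explicit distributions are available.
- **Independent variables by default,** with an optional latent-class
  mixture (per-class permuted category distributions) to induce dependence.
- **Seeding:** each area uses an independent seeded stream, so changing the
  number of areas does not perturb the areas already generated.

Ground truth is always computed by exact counting on the full population.

What the generator does **not** emulate: real joint demographic
distributions (age–income–schooling dependence), household structure, and
geography (no census-tract-to-FSA assignment). Consequently, passing tests
demonstrate that the estimators and fits are *correct and well calibrated
under the stated sampling model*, not that any particular real FSA has a
given uniqueness; the published evaluation metrics of the original census
analysis are functions of restricted data and are treated as regime
descriptors, not reproduction targets.

### Problem sizes used in the test suite

Chosen to exercise each property at the smallest scale where it is
informative: estimator recovery on 30 areas of 1,000–20,000 people;
coefficient recovery at n = 50,000 observations; the cross-validation and
suppression studies on a 40-area population spanning the full 200–78,457
range with all 2–3 member models (3,520 observations, I05 prevalence
≈ 0.37).

## Suppression reports

A report flags each area of a record-level dataset under one rule — a
fitted/published 5% or 20% model, or the 0% rule (area flagged when the
Zayatz estimate is positive, the stringent prior practice) — and totals the
records in flagged areas. Missing population entries abort with the
offending area codes listed. On synthetic datasets the suppression
percentages are monotone, 0% ≥ 5% ≥ 20%: permitting a higher uniqueness
threshold never suppresses more data.

## Known limitations

- The Zayatz estimator's upward bias grows as the sampling fraction falls;
  below ~10% a different estimator should be considered (the
  Poisson–gamma/Bethlehem family is deliberately out of scope).
- The naive spectrum step estimates the population class-size distribution
  by the sample's; areas with very few sampled records yield coarse spectra
  and noisy estimates.
- Published models ship without centers and cannot be applied until the
  user supplies them; this is a fidelity choice, not an oversight.
- MaxCombs requires finite category counts; continuous variables must be
  discretized before they can enter a scheme.
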