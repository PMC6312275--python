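# Methods

## The analysis

`clonecast` models a molecular response to checkpoint-inhibitor therapy —
the log count of tumor-infiltrating lymphocyte (TIL) clones that expand in
peripheral blood after anti-PD-L1 treatment — from attributes measured
before treatment. The setting is a small cohort (n ≈ 21) with more encoded
features (p = 36) than patients, so every design choice is about honest
error estimation under p > n.

**Response.** y_i = log(1 + c_i), where c_i is patient i's expanded-clone
count. The pseudocount (default 1) keeps the transform defined at zero
expansion, and the base (e by default, 10 optionally) is recorded in run
metadata; both only rescale/shift the response and do not change variance
explained.

**Design.** Each binary attribute contributes one 0/1 column; each
continuous attribute contributes the pair (x, log(1+x)), letting the linear
model capture saturating dose-response shapes. The default 19-attribute
schema (7 clinical, 7 tumor, 5 circulating; 2 binary) encodes to
2 + 17 × 2 = 36 columns. A missing attribute value propagates to both
derived columns.

**Preprocessing** is fitted on training rows only, inside every
cross-validation fold: per-column median imputation (midpoint convention for
even counts) followed by standardization to mean 0, standard deviation 1
(denominator n; configurable to n−1 — which of the two the original
analysis used is not determinable, and the choice is immaterial after the
penalty rescaling). Binary columns are standardized like the rest, matching
the behavior of built-in normalization in standard elastic-net fitters.
A zero-variance training column gets a scale guard of 1, making it exactly
zero after centering instead of dividing by zero.

**Model.** The elastic net minimizes

    (1/2n) Σᵢ (yᵢ − β₀ − xᵢ·β)² + λ [ρ‖β‖₁ + ((1−ρ)/2)‖β‖₂²]

with unpenalized intercept. ρ is searched over {0.1, 0.5, 0.7, 0.9, 0.95,
0.99}; for each ρ, λ runs over a geometric path of 100 values from
λ_max(ρ) = maxⱼ |Σᵢ xᵢⱼ(yᵢ − ȳ)| / (nρ) down to λ_max × 10⁻³. Each
(ρ, λ) is scored by leave-one-out CV *within the training data* (k-fold is
available as a config option) and the winner refit on all training rows.
Ties within 10⁻¹² of the minimal inner-CV error resolve to the largest λ,
then the smallest ρ — the sparser, more regularized model. A 1000-tree
random forest and an intercept-only mean model are provided as comparators
with the same contract; the forest is known to overfit badly at this n and
is excluded from headline analyses.

**Evaluation.** Outer leave-one-out: for each patient, the entire pipeline
(imputation, scaling, hyperparameter search, refit) is fitted on the other
n−1 patients, and the withheld patient predicted. Held-out variance
explained is 1 − MSE_loocv / baseline, where the baseline is the in-sample
MSE of predicting the mean response for everyone (denominator n) — i.e. the
empirical response variance. Raw values can be negative (a pipeline can be
worse than the mean); "nominal" values clamp at 0 for reporting, and both
are always retained. Training-set error is never reported as a performance
measure. Fold order is patient order; per-fold RNG streams are keyed on
(seed, patient id) so results are independent of fold execution order.

**Inference.** Two permutation tests share one statistic, the LOOCV MSE,
with the one-sided add-one p-value p = (#{null ≤ observed} + 1)/(B + 1) —
the exact-valid convention. The response test permutes responses across
patients uniformly; the category test applies a single patient permutation
jointly to all raw attributes of one category (clinical, tumor, or
circulating) before encoding, so each (x, log1p x) pair and the
within-category correlation structure move coherently, while all features
remain available to the model — a conditional test of that category's added
value. Every replicate re-runs the full pipeline including hyperparameter
selection. For the response test the per-fold preprocessors are computed
once and shared across replicates; this is exact, not an approximation,
because imputation and scaling depend only on the features, which the
response permutation does not touch. No multiplicity adjustment is applied
across the three category tests; report them as a family.

**Triage.** For a higher-is-better biomarker, the threshold is the minimum
score among DCB patients (DCB = progression-free survival ≥ 6 months,
supplied as a label); non-DCB patients at or above it count as treated —
ties included, so 100% DCB capture holds under any tie structure. The
reported fraction equals the exhaustive minimum over all thresholds and
depends only on score ranks; the quoted percentile is the share of non-DCB
patients strictly below the threshold. Patients missing a biomarker are
excluded from that biomarker's triage only.

## The solver

The elastic-net kernel is an exact active-set method (feature-sign search)
on the Gram statistics G = X'X/n, c = X'y/n: it maintains the support and
sign pattern, solves the stationarity system (G_AA + λ(1−ρ)I) β_A =
c_A − λρ·sign_A exactly, and handles sign flips by an objective-decreasing
line search over zero crossings. A coordinate enters the support only when
its smooth-gradient magnitude exceeds λρ + tol, so `tolerance` (default
10⁻⁷) bounds the KKT slack. A 10⁻¹² diagonal jitter keeps pure-lasso solves
on exactly collinear supports nonsingular.

This choice is deliberate: the design's (x, log1p x) pairs are nearly
collinear (correlations often > 0.999), and first-order coordinate descent
slows to a crawl in the resulting flat valleys, while active-set steps
converge combinatorially — a handful of ≤ 36 × 36 linear solves per path
point. The solver is validated in the test suite against closed forms
(ordinary least squares at vanishing λ, soft-thresholding on orthonormal
designs at ρ = 1, the ridge normal equations at ρ = 0, the exact-zero model
at λ ≥ λ_max) and against an independent reference coordinate-descent
implementation on the ill-conditioned cohort design itself. Paths are
warm-started from large to small λ; the outer LOOCV loop and the inner CV
are fused into compiled code, which is what makes full-pipeline permutation
tests (10⁴–10⁵ nested fits) run in minutes on one CPU. The fused loop and
fold-by-fold fitting through the public API are the same computation, and a
test asserts their equality.

## The synthetic cohort generator

The generator provides study-shaped data with known ground truth:

- **Attributes** are drawn independently per patient from per-attribute
  marginal families — Bernoulli for the two binaries (prior BCG q = 0.35,
  albumin < 4 q = 0.3), rounded log-normals for counts (e.g. missense SNV
  count: median ≈ 180, sd(log) = 0.55; ages ~66 ± 8 y), scaled Betas for
  fractions and clonalities (e.g. T-cell fractions ≈ 0.1–0.35). Spreads
  describe within-cohort variation for a single histology, not
  across-cancer-type ranges.
- **Signal**: `support_size` (default 4) log1p-encoded columns, selected
  uniformly (optionally restricted to chosen categories), receive
  coefficients of magnitude `coefficient_scale` (default 0.4) with random
  signs, on the standardized encoded design. With four ±0.4 effects the
  response variance lands near 0.85 — the scale a real log-expansion cohort
  exhibits.
- **Noise**: σ is set from `target_oracle_ve` (default 0.8) via
  σ² = Var(lp)(1−VE)/VE, so the noiseless signal explains 80% of response
  variance — strong but imperfect. The intercept (default 3.2, counts
  ~25) keeps counts high enough that rounding the count back from the
  continuous response adds little extra noise; at low intercepts the
  realized ceiling falls visibly below the configured VE. For null cohorts
  (k = 0) σ defaults to 0.9.
- **Labels and comparators**: DCB ~ Bernoulli(logistic(2·z)) on the
  standardized signal (positively linked to expansion); PD-L1 staining is
  generated as a weakly signal-linked percentage and carried only as a
  comparator, never a model input.
- **Missingness**: completely-at-random masking at rate 0.05 on attributes
  whose schema allows it (the binaries do not), with a guard keeping every
  column imputable.

Everything derives from one seed through named substreams; identical seeds
give byte-identical cohorts.

**What it does not emulate** — and therefore what passing tests do not
show: the joint covariance of real attributes (real mutation/neoantigen
counts are mechanically correlated; here attributes are independent),
informative missingness, measurement error on the attributes, batch or
center effects, and any nonlinearity beyond the log1p encoding. Power and
recovery results on this generator characterize the pipeline under a
sparse, independent-attribute regime; real cohorts with correlated feature
blocks can be easier (signal spread over proxies) or harder (confounding)
than this.

At the default study scale the pipeline's held-out accuracy is modest and
volatile across draws — a minority of cohorts show negative raw VE, driven
by single held-out patients at high leverage when the inner-LOO selection
favors a nearly unpenalized fit. This mirrors the instability any
LOO-selected high-dimensional fit has at n = 21 and is the reason the
package always reports raw alongside clamped variance explained.

## Problem sizes in the shipped tests and acceptance script

The test suite exercises the permutation machinery at B = 99 with a reduced
hyperparameter search (`FAST_ENET_CONFIG`; selection logic identical),
calibration on 200 null cohorts, and power/recovery on 20 default cohorts
with the full search. The acceptance script runs the complete analysis on
one default cohort with B = 99 (response) and B = 49 (per category). These
sizes are the package's own trade-off between Monte-Carlo resolution and a
few minutes of single-CPU runtime; the library supports B = 1000 and larger
grids unchanged.

## Known limitations

- The category permutation acts on raw attributes pre-encoding; permuting
  encoded columns independently would break (x, log1p x) coherence and is
  deliberately not offered.
- With B permutations the smallest attainable p is 1/(B+1); choose B
  accordingly.
- The triage statistic is a sensitivity-at-full-recall rank statistic; it
  is not an ROC/AUC analysis and intentionally ignores costs of treating
  DCB patients late or not at all.
- LOOCV variance explained at n = 21 has large sampling variance; single
  numbers should be read with the permutation p-value, not alone.
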