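# Methods

## Outcome model and dichotomization

The modelled outcome is the 90-day modified Rankin Scale collapsed to a
binary label: mRS 0–2 → good (0), mRS 3–6 → bad (1). All model families
estimate P(bad | covariates); any mRS value outside {0..6} is rejected at
the dichotomization boundary rather than silently clipped.

## Synthetic cohort generator

The generator exists because the original patient-level data are
access-restricted; it emulates the published cohort summary so that every
downstream stage is testable against a known ground truth.

**Feature marginals.** Features are drawn through a latent-Gaussian
copula: a 7-dimensional standard normal with exchangeable correlation
r = 0.15 (weak but non-trivial; the implied VIFs are ≈ 1.05, far under
the 1.91 ceiling the analysis assumes), each coordinate mapped through a
marginal quantile transform:

* `age` — normal with center 72 and sd 15/1.349 (IQR of a normal is
  1.349 sd, so the IQR is 15 years);
* `nihss` — a shifted gamma, shape 1.05, scale 4.2, shift −0.45, rounded
  to integers and left-truncated at 0. The published summary fixes only
  the median (3) and IQR (5) of this right-skewed integer score; the
  gamma family and its parameters are the package's calibration (fitted
  numerically at n = 2×10⁶; the discrete marginal hits median 3 / IQR 5
  exactly);
* the five binary covariates — thresholded at their target prevalences
  118/314 (male sex), 84/314 (cardiac history), 79/314 (diabetes),
  182/314 (hypercholesterolemia), 74/314 (thrombolysis).

**Planted outcome.** The bad-outcome probability is logistic in the
z-scored features (empirical mean / population sd of the generated
sample): coefficients +1.0 for the age and NIHSS analogues, ±0.25 for
the rest (cardiac, diabetes, male sex positive; hypercholesterolemia and
thrombolysis negative), intercept −1.298 calibrated numerically so the
expected prevalence is 88/314 ≈ 0.280. The magnitudes encode the
domain-knowledge baseline that age and stroke severity dominate 90-day
outcome; the published analysis reports no effect sizes, so the values
are the package's choice and are exposed to tests via `cohort.truth`.
The mRS itself is sampled by drawing the binary outcome first and then a
uniform value inside the matching half, so dichotomization reproduces the
planted probability exactly. Missingness is applied completely at random
(default cell rate 0.02, capped at 0.05 to mirror the cohort's inclusion
rule).

`planted_truth_auc` gives the Monte-Carlo AUC of the true linear
predictor on fresh data (≈ 0.835 under the defaults) — the ceiling
against which pipeline performance is checked.

**What the generator does not emulate:** imaging covariates, follow-up
loss, informative missingness, measurement error in NIHSS, or any
feature-outcome nonlinearity. Passing recovery tests therefore shows the
machinery is correct under a faithful-but-idealized data-generating
process, not that the clinical conclusions transfer to any particular
real cohort.

## Preprocessing protocol

Per shuffle, in order: (1) uniform random 4:1 split (test size
round(n/5)); (2) imputation with train means (continuous) and train
modes (binary), then z-scoring with train mean/sd — both applied
unchanged to the test partition, so no test statistic ever enters the
state; (3) random down-sampling of the training majority class to the
minority count. Binary features are scaled together with continuous ones
for cross-model comparability (trees are scale-invariant, so this is
harmless there). Internal statistics are computed with numpy on an
extracted array so the fitted state is bitwise-independent of the
DataFrame's memory layout. The VIF screen (1/(1−R²) per feature, OLS
with intercept) runs on complete cases of the raw cohort.

## Model families

* **GLM / Lasso / elastic net** — scikit-learn's LogisticRegression
  (lbfgs for the smooth problem; seeded saga for L1 terms; tolerance
  1e−8). Lasso is parameterized by the inverse strength C; the elastic
  net by a total strength α and l1-ratio, with the sklearn convention
  α(l1_ratio‖β‖₁ + (1−l1_ratio)/2‖β‖₂²) on the summed loss, so
  l1_ratio = 1 coincides with Lasso at C = 1/α. Intercepts are never
  penalized.
* **GBDT** — written in-package: stagewise boosting of depth-limited
  regression trees on the logistic loss. Trees are fitted to the current
  negative gradients with greedy weighted-variance-reducing splits; leaf
  values are L2-regularized Newton steps (penalty λ on leaf weights),
  optionally refined by further Newton iterations on the updated margins.
  The bagging temperature t draws per-tree observation weights
  u = e^t, e ~ Exp(1), normalized to mean 1 (t = 0 → deterministic
  boosting). A leaf-count penalty γ exists in the interface but defaults
  to 0 — depth is the capacity control that is actually tuned. Default
  500 trees with early stopping (20 stalled rounds) on an internal 10%
  validation slice.
* **MLP** — one rectified hidden layer, 2-way softmax head, minibatch
  SGD on cross-entropy + L1 penalty. Dropout is classic: hidden units
  dropped at rate DR during training without rescaling, hidden outputs
  weighted by (1−DR) at inference. He-initialized, seeded, capped at 300
  epochs with early stop after 20 epochs without loss improvement. The
  rectifier is chosen for the hidden layer because the z⁺ relevance rule
  assumes non-negative activations.

Hyperparameter tuning is exhaustive grid search with seeded 10-fold CV
on the balanced training set (unstratified folds), selecting the highest
mean validation AUC; ties break toward stronger regularization, then
grid order. A single-candidate grid skips the fold loop. The default
grids are the study protocol's ranges (50 Lasso C values from 0.10 to
1000; a 20×11 elastic-net lattice; depth {2,4} × learning rate
{0.03,0.1,0.3} × bagging temperature {0.6,0.8,1.0} × λ {3,10,100,500} ×
leaf iterations {1,2}; hidden units {5,10,15,20} × learning rate
{0.001,0.01} × batch {16,32} × dropout {0.1,0.2} × L1 {0.0001,0.001});
tree count and epoch cap are not tuned.

## Interpretability

**Linear models.** Raw importance is the coefficient vector on the
standardized features (intercept excluded); meaningful because the
features are near-orthogonal by construction.

**Exact Shapley values.** Computed on the probability scale for test
observations by full 2^|F| subset enumeration (|F| = 7 here; capped at
15). The value function is interventional: v(S) is the mean prediction
over a seeded 100-row background sample from the balanced training set
with the features in S pinned to the explained observation's values.
Efficiency, symmetry, dummy and linearity are verified computationally
to 1e−9, and the enumeration is cross-checked against an independent
permutation-sampling estimator.

**Deep Taylor / LRP.** Relevance is seeded at the bad-outcome output
neuron with value P(bad) and propagated with the z⁺ rule (positive
weights only, biases excluded from the denominators, zero-denominator
neurons propagate nothing), which conserves the seeded total exactly.
Seeding at the *predicted* class is available as an option but is not
the default: it mixes two different explananda (P(bad) for some
observations, P(good) for others), and in recovery experiments it
produced training-seed-dependent rankings, whereas the fixed bad-outcome
seeding decomposes the same quantity the other families' importances
refer to. Per-feature relevances are aggregated with confidence weights
θᵢ = yᵢPᵢ + (1−yᵢ)(1−Pᵢ).

**Aggregation and normalization.** By default the pipeline takes
absolute values per observation before averaging Shapley values and
relevances. The signed alternative (`abs_per_observation=False`) is
kept, but for monotone effects the signed interventional attributions of
an effect are positive for above-average and negative for below-average
feature values, so their mean over a test set cancels toward zero as n
grows — empirically the planted NIHSS effect's signed rating collapsed
to ~0.002 at n = 5,000 while the absolute rating correctly placed it on
top. Note that z-scored inputs make individual relevances sign-indefinite
(the z⁺ conservation guarantees apply to non-negative activations), which
is a further reason the absolute aggregation is the default. Final
ratings: per shuffle, |scores| scaled to unit sum; across shuffles,
per-feature mean ± SD. All-zero vectors are excluded with a warning.

## Performance assessment

AUC is the rank-based Mann–Whitney statistic with ties counted ½
(identical to trapezoidal ROC integration); cross-checked against an
independent implementation in the tests. Across shuffles the median and
IQR are reported per model and partition, with quantiles by linear
interpolation between order statistics.

## Reproducibility

Every random draw descends from a master seed through counter-based
`SeedSequence` spawning (one stream per shuffle), so shuffles are
independent, individually re-runnable, and the experiment report —
including the CSV artifacts on disk — is a pure function of (config,
cohort). Per-shuffle seeds are logged to `seeds.csv`.

## Problem sizes used in the checks

The shipped verification runs use: n = 5,000 cohorts with 10 shuffles
and reduced grids (two candidates for the penalized linear families, one
mid-grid configuration for GBDT and MLP) for rank-recovery; twelve
replicate n = 10,000 cohorts for coefficient recovery (at that n the
per-fit sampling error is ~9% of the weakest planted effect, so the
recovery check targets the bias of the averaged estimate, keeping the
10% band meaningful); n = 2,000 with 10 shuffles for the
performance-vs-ceiling and null-signal checks; and the study-scale
n = 314 with 20 shuffles in `scripts/acceptance.py`. These sizes are the
package's own balance between statistical resolution and a desk-scale
run.

## Known limitations

* The GBDT reproduces the printed boosting equations, not any specific
  library's internals (no ordered boosting, no categorical target
  statistics, no oblivious trees).
* Exact Shapley enumeration is exponential in |F|; beyond 15 features a
  sampling approximation (not included) is required.
* The z⁺ rule's non-negativity guarantees do not hold for z-scored
  inputs; relevances are interpreted through the absolute-value
  normalization.
* Tuning-grid defaults assume the balanced training set is large enough
  for 10-fold CV; single-class folds are skipped with a warning.
* The null-signal AUC check has binomial/rank noise of a few hundredths
  at the sizes used; its tolerance (±0.08) reflects that, not a model
  deficiency.
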