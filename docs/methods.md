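# Methods

## The statistical problem

A yeast gene-deletion experiment crosses a binary chromosomal factor (gene
deleted vs. wild-type allele) with a binary non-chromosomal factor — either
the presence of the cytoplasmic dsRNA killer virus ([kil-k] vs. [kil-0]) or
the source of the mitochondrial genome (Sigma vs. S288c) — and measures
colony size in 9–20 replicates per genotype cell.  The question is how much
replicate-to-replicate variance ("heritability" in this proxy sense) is
explained by the chromosomal factor alone, by adding the cytoplasmic factor,
and by adding their interaction — and which of these predictors the data
actually support.

## Response transform

Colony sizes `c_ij > 0` are analysed as `y_ij = c_ij^0.25`, a
variance-stabilising power transform.  The pure power form is used rather
than `(c^l - 1)/l`; the two differ by a fixed affine map, which leaves R²,
adjusted R², MSE ranking and every selection event unchanged, so the simpler
form is preferred.  The exponent is a configuration value (default 0.25); no
profile-likelihood estimation of the exponent is attempted.

## Nested linear models and resampled comparison

Three 0/1-coded models are fitted by OLS:

    simple       y = b0 + b1*X1
    additive     y = b0 + b1*X1 + b2*X2
    interaction  y = b0 + b1*X1 + b2*X2 + b3*X1*X2

with X1 = 1 for the deletion and X2 = 1 for the virus-present / Sigma state
by default (the coding is configurable and recorded, because selection
frequencies of the interaction column can depend on it).  Fit quality uses
`R² = 1 − RSS/TSS` and the adjusted `Ra² = 1 − (RSS/(n−q−1))/(TSS/(n−1))`,
which penalises model size.

Each repeat splits every genotype cell into equal training/test halves (odd
counts: the extra replicate trains), fits the three models on the training
half, and records (i) the model with the lowest test MSE and (ii) each
model's *out-of-sample* adjusted R² (TSS about the test-set mean,
n = n_test).  Out-of-sample Ra² is the headline statistic because its SD
across sampled test sets is a per-test-set quantity; the training-half Ra²
is also recorded for comparison.  MSE ties go to the smaller model.
Negative out-of-sample Ra² values are reported, not clamped.  The default is
1000 repeats; with n ≤ 80 rows this takes a few seconds.

An important consequence of this design (shared with the original analysis):
frequencies are **conditional on the one realised dataset**.  A coefficient
whose true value is zero but whose realised estimate is ~2 SE away will be
selected in most splits of that table, legitimately.  Distribution-level
statements (type-I error, power) must average over fresh datasets, which is
what `recovery_suite` does (below).

## LASSO with BIC

The penalised criterion is `RSS + lambda * ||beta||_1` on predictors scaled
to unit sample variance with a centred response; the intercept is
unpenalised.  Coordinate descent with warm starts runs over a 100-point
log-spaced grid from `lambda_max = 2*max_j |x_j'y|` down to `1e-3 *
lambda_max`; convergence is declared when the largest coefficient change
falls below 1e-9.  Exact zeros come from the soft-threshold operator itself,
never from post-hoc rounding.

Each path point is scored by the per-observation BIC
`(RSS + log(n) * q * sigma2_hat)/n` with `q` the support size; ties go to
the larger penalty (sparser fit).  Two conventions are implemented for the
RSS (the LASSO fit's own RSS — default — or the OLS refit on its support)
and two for `sigma2_hat` (residual variance of the full interaction OLS fit
— default — or refit-per-support).  The defaults are what the resampling
pipeline uses; the refit convention is the one with the exact
noiseless-recovery property (with `sigma2_hat = 0` its RSS reaches zero at a
perfectly fitting support and the sparser tie wins), whereas under the
lasso-RSS convention shrinkage keeps RSS positive along the whole path.
Note also that with 0/1 factorial coding the X2 and X1X2 columns correlate
(~0.58 in balanced designs), so the path can introduce a surrogate before
the truly generating predictor; selection events are therefore about
supports, not causal attribution.

## Strong-hierarchy interaction lasso

The two-way interaction model

    y = b0 + sum_j beta_j X_j + (1/2) sum_{j != k} theta_jk X_j X_k + eps

(with Theta symmetric, zero diagonal; for two factors the single free entry
theta_12 equals the coefficient of the X1*X2 column, since the ordered-pair
sum and the 1/2 factor cancel) is estimated by the all-pairs lasso

    min  (1/2)*RSS + lambda*||beta||_1 + (lambda/2)*||Theta||_1

under the strong-hierarchy restriction that an interaction enters only when
both main effects do.  The restriction is imposed through the standard
convex relaxation: each main effect splits into non-negative parts
`beta_j = b_j+ − b_j−` with constraints `||Theta_j||_1 <= b_j+ + b_j−`.  For
p = 2 the resulting QP (seven variables, two coupling constraints) is solved
by accelerated projected proximal gradient; the projection onto the
constraint set is computed exactly by a KKT case analysis with bisection,
and boundary ties are snapped to exact zeros inside the operator so active
sets are exact.  An independent high-precision reference — SLSQP solves of
the five hierarchy-feasible restricted supports (∅, {1}, {2}, {1,2},
{1,2,12}) — serves as a global-optimality oracle and exact fallback; the
solver matches it to 1e-6 on random instances.  The solver addresses the
two-factor design this analysis uses; more factors raise
`NotImplementedError`.

The penalty grid has 20 log-spaced values from the smallest
all-zero-optimal penalty (`max(|x1'r|, |x2'r|, (|x1'r|+|x2'r|+|x12'r|)/3)`
on standardized data) down to 1% of it.  The penalty is chosen by k-fold
cross-validation (default 5 folds, fold assignment balanced within genotype
cells so every training part sees all four cells) with the
one-standard-error rule: the largest penalty whose mean held-out MSE is
within one SE (over folds) of the minimum; the final model is refit on all
rows at that penalty.  The repeated-selection harness re-randomises fold
assignment each repeat on the full per-experiment data by default
(half-split training data is available as an option).

## Synthetic experiments

The generator inverts the modelling chain: on the transformed scale each
replicate in cell (x1, x2) is `y ~ Normal(b0 + b1*x1 + b2*x2 + b3*x1*x2,
sigma^2)` and the raw size is `y^4` (for the default exponent 0.25).  Noise
lives on the transformed scale — where the models assume Gaussian errors —
so recovery targets are exact.  Per-cell replicate counts default to
uniform draws from 9–20, matching the deletion assays' range.  Non-positive
transformed draws are redrawn (they correspond to impossible colony sizes);
configurations whose cell means are non-positive are rejected outright.

`reference_conditions` freezes five named regimes used as fixtures, with a
baseline of `b0 = 4.0` (colony size 256) and `sigma = 0.2` chosen as
realistic for transformed colony sizes:

| condition                  | b1    | b2   | b3   | sigma | regime |
|----------------------------|-------|------|------|-------|--------|
| control_weak_chromosomal   | 0.10  | 0    | 0    | 0.20  | control, weak chromosomal effect only |
| strong_interaction         | −0.80 | 0.30 | 1.00 | 0.20  | all effects clear; interaction at 5 sigma |
| main_plus_interaction      | −1.00 | 0.02 | 0.80 | 0.20  | strong deletion + interaction, null cytoplasmic main effect |
| interaction_dominant       | −0.12 | 0.06 | 0.50 | 0.20  | interaction-led; main effects at the half-split detection limit |
| near_null                  | 0.03  | 0.02 | 0    | 0.25  | essentially no genotype signal |

The main-effect sizes of `interaction_dominant` were placed at the
approximate BIC detection threshold for half-split sample sizes
(`|b| ≈ sigma * sqrt(log(n)/ (n*var(x)))` ≈ 0.7*sigma at n ≈ 28), reasoning
from the design rather than from any fitted data.  These are fixture
choices: the generator makes no attempt to match the moments of real colony
measurements, and passing tests on these regimes demonstrates the
machinery's behaviour under the model's own assumptions — not distributional
features of real colony data (outliers, heteroscedasticity on the raw
scale, plate effects), which the generator deliberately omits.

`recovery_suite` differs from the resampling harness in one deliberate way:
every repeat draws a *fresh* table and runs one modelling pass, so its
frequencies are operating characteristics (type-I rate, power) of the whole
procedure over the generator distribution, free of single-realisation
conditioning.

## Seeds and reproducibility

All randomness flows through `numpy.random.default_rng` seeded by a
counter-based schedule `SeedSequence([master_seed, repeat_index])`, so any
single repeat can be re-run in isolation and every summary is
bit-reproducible given its master seed.  Split, fold-assignment and
generator streams are independent.

## Numerical choices and degenerate inputs

* OLS uses `lstsq` on the intercept-augmented design; rank deficiency and
  `n < p + 2` are rejected with specific errors.
* Coordinate descent tolerance 1e-9 (max coefficient change), iteration cap
  1e5; the hierarchy solver uses tolerance 1e-10 with the same cap, and its
  step size is the inverse largest eigenvalue of the split-design Gram
  matrix.
* `lambda_max` values are nudged up by one part in 1e12 so the boundary
  fit is exactly empty despite summation-order differences.
* Splits/folds that would leave a constant predictor column or too few rows
  are redrawn with fresh derived seeds up to a retry cap and counted in the
  summary (`resamples`).
* MSE ties in model comparison go to the smaller model; BIC and CV-minimum
  ties go to the larger penalty.

## Known limitations

* The hierarchy solver is specialised to two binary factors (the design of
  this analysis); it is not a general hierNet replacement.
* Selection frequencies on a fixed table are realisation-conditional (see
  above); only `recovery_suite` frequencies have frequentist operating-
  characteristic interpretations.
* The generator's Gaussian-on-transformed-scale model is the analysis
  model; it cannot reveal transform misspecification.
* Experiments that vary mitochondria within a fixed virus state are treated
  as separate experiments with a single binary non-chromosomal factor each.
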