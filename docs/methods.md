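# Methods

## Model and pipeline

The package estimates how risk factors and their second-/third-order
interactions associate with a binary disease outcome. The statistical model
is Bayesian logistic regression: y_i ~ Bernoulli(F(β₀ + Σ_k β_k X_ik)) with
F the standard logistic function and an improper uniform prior on every
coefficient. The flat prior makes the log-posterior equal the
log-likelihood, so the posterior mode coincides with the maximum-likelihood
estimate — a property the test suite exploits, and the reason a fast
deterministic Newton (IRLS) fit can stand in for the sampler inside the
feature-selection loop.

Because the interacted design (489 columns from 14 variables) is heavily
collinear, regression is performed not on the columns themselves but on the
synthetic variables of a factor analysis of mixed data (FAMD), with
sub-unit-variance components dropped, and a genetic algorithm selects the
subset of synthetic variables with the best smoothed validation AUC. The
selected posterior is finally mapped back to per-variable odds multipliers.

## Synthetic cohort generator

The generator emulates the marginal structure of the study population:

| variable | marginal | bounds | bound handling |
|---|---|---|---|
| age | 45.6 (16.9) | 18–80 | censored (top/bottom-coding) |
| BMI | 28.7 (6.65) | 14–70 | truncated (rejection) |
| PHQ depression score | 2.89 (4.03) | 0–27 | censored |
| sleep hours | 7.01 (1.44) | 1–12 | censored |
| income-to-poverty ratio | 2.50 (1.64) | 0–5 | censored |
| systolic BP | 123 (17.9) | 80–230 | truncated |
| male / gout / diabetes / smoked | 0.523 / 0.030 / 0.106 / 0.428 | — | — |
| ethnicity (MA/OH/black/white/ONH) | .163/.105/.208/.410/.114 | — | white = reference |

Censoring (clipping at the bounds) rather than rejection is used wherever
the real instrument top- or bottom-codes: survey age is top-coded at 80,
the income-to-poverty ratio at 5, sleep at 12 h, and the depression score
floors at 0. This is not cosmetic — no truncated normal (indeed no
log-concave law) on [0, 5] can reach the income ratio's stated sd of 1.64
(the uniform bound is 5/√12 ≈ 1.44); the boundary mass of the censored
normal can. For each continuous variable the parent (μ, σ) is solved
numerically so that the post-bound moments equal the stated mean/sd;
unattainable targets raise a schema error. The depression score is treated
as a quasi-continuous censored normal rather than a sum of independent
ordinal items: independent items bounded 0–3 with the stated mean cannot
exceed sd ≈ 0.9·√9 ≈ 2.8, far below the observed 4.03 (real questionnaire
items are strongly correlated).

Risk factors are independent by default; an optional Gaussian copula
(correlation over the continuous variables and latent binary thresholds)
supports stress tests. The joint distribution is an artifact choice — the
study tables publish only marginals.

The ground truth is a sparse logistic model whose effects are log-odds per
standard deviation of the *term column* (products formed first, then
standardized; binary and pure-binary-product columns standardized by their
0/1 sd for this purpose). This matches the reporting convention of the
analysis — odds multipliers per one-SD increase of the variable — so the
injected truth and the pipeline's output live in one basis. The default
truth is age +0.5, age·BMI +0.4, male·ONH −0.4 with an intercept targeting
the study's 6.58% outcome prevalence.

What the generator does *not* emulate: multistage survey sampling and
sample weights (deliberately out of scope), item-level missingness patterns
(only a uniform missingness switch), measurement error, and any real
dependence structure between risk factors. Passing recovery tests on these
cohorts therefore demonstrates correctness of the machinery under known
ground truth, not performance on real survey data.

## Preprocessing decisions

- Standardization is applied to interaction columns *after* the product is
  formed, so every reported effect is per SD of the (interacted) column
  itself. The alternative order (standardize bases, then multiply) is
  easily composed from the same primitives but is not the default, since
  reported effects are explicitly per-SD of the variable.
- Pure binary×binary products remain on {0,1} and enter FAMD as qualitative
  (disjunctively coded) columns; any product involving a continuous base is
  quantitative. Columns constant on the training split (empty rare-binary
  cells in small cohorts) are dropped and logged.
- Raw-table derivation: depression = sum of the nine questionnaire items
  (0–27), BP = mean of four readings, sleep capped at 12, participants aged
  ≤ 17 excluded, complete-case filtering with logged counts.

## FAMD

Quantitative columns are standardized (population sd); each qualitative
state indicator is divided by √(state proportion) and centered — the
standard construction that makes total inertia equal #quantitative +
#states − #qualitative variables. Eigenvalues are σ²/n from the SVD of the
assembled matrix; scores are MV; retention keeps eigenvalues strictly > 1
(the average inertia per axis; equality is measure-zero). Component signs
are fixed so each right singular vector's largest-magnitude entry is
positive, for reproducibility across linear-algebra backends. Held-out data
are projected with training centers/weights; unseen qualitative states
raise an error naming the state.

## Sampler

Since the flat-prior posterior's geometry is the logistic likelihood's, the
HMC sampler preconditions with the diagonal observed information at the
MLE (falling back to the Fisher information at β = 0 under separation),
draws jittered leapfrog trajectory lengths, adapts a shared step size by
dual averaging during warmup (default 1,000 iterations, discarded), and
runs all chains as one vectorized batch. Defaults are 8 chains × 400
retained draws. Convergence is gated on split-R̂ < 1.1 for every parameter;
failure raises an error carrying the offending R̂ values rather than
returning results. Posterior predicted probabilities are the mean over
draws of the per-draw probability (the quantity the ROC consumes), not the
probability at the mean coefficient.

The Newton/IRLS mode uses minimum-norm steps (lstsq), so rank-deficient
subsets — duplicated or collinear columns — still yield well-defined
predictions; separation is flagged as non-convergence and scored as
no-signal fitness (0.5) by the GA.

## ROC smoothing and uncertainty

The binormal fit drops vertices with TPR or FPR in {0, 1} (infinite
probits) and requires ≥ 3 interior vertices; perfect separation therefore
has no probit fit, and the smoothed AUC falls back to the empirical AUC
(the two coincide at 1 in that limit). The probit regression is unweighted
OLS. Radial bands parameterize the curve as (FPR, TPR) = (1 − r·cosθ,
r·sinθ); r(θ) is solved by vectorized bisection (60 iterations), with the
θ = 0 and θ = π/2 rays clipped to the axis intersections (r = 1). Bootstrap
resamples (score, label) pairs jointly without stratification; single-class
replicates are redrawn and counted. Percentile intervals are used; the
bands/intervals are clamped to contain the point estimate (a finite-
replicate safeguard).

## Genetic algorithm

Rank-selection probabilities use zero-based ranks, p_i = [min + (max −
min)·i/(n−1)]/n, so that probabilities sum to exactly 1 and the worst/best
expected selection counts are exactly min and max. (With literal ranks
1..n the probabilities sum to more than 1.) Mutation is a single uniformly
chosen bit flip applied with per-genome probability 0.1 — the smallest move
consistent with the stated rate. The forced prefix (first seven synthetic
variables at full scale) applies to initialization only. Fitness is
memoized by bit pattern; ties are broken by smaller subset, then
lexicographic genome order, making runs bit-reproducible in MLE-fitness
mode. Elitism copies the top 5% unchanged, so the per-generation maximum
fitness is non-decreasing by construction.

Full-scale settings (population 500, 200 generations) reproduce the
original computational design; the desk-scale default (population 50, 25
generations) and the test configurations (population 16–40, 5–30
generations) are sized so the whole suite and the acceptance script run in
minutes on one CPU. The recovery experiment uses n = 10,000 cohorts,
population 24 × 8 generations, 300 warmup iterations and 200–500 bootstrap
replicates for the same reason; these sizes are stated here as the
package's chosen study conditions.

## Coefficient reconstruction and its limits

B = AVᵀ (V restricted to retained components, unselected columns of A
zeroed) reproduces the synthetic-space linear predictor exactly — per draw,
scores·a = M·(V_r a) — which is the defining identity tested to 1e-8.
Indicator coefficients are de-weighted by 1/√(state proportion) before
differencing, so a binary's effect is the log-odds change for flipping the
variable; multiplying by the column's 0/1 sd expresses it per SD, the scale
on which all variables are ranked. Ranking sorts by the posterior
probability that the odds multiplier lies on its median's side of 1, with
ties broken by |log median| (so protective and risk effects are treated
symmetrically) and then by name for determinism.

**Known limitation — projection shrinkage.** Retention makes B a rank-m
projection of the coefficient vector: B = (V_r V_rᵀ)β for any β the data
identify. Correlated columns (age with age², age·BMI, age·smoked, …) share
their variance in a few retained components while the column-specific
directions live in the discarded sub-unit-variance components, so a sparse
true effect is smeared across its column family and each individual
reconstructed coefficient is strongly shrunk toward 1 on the odds scale —
empirically by a factor of 4–10 on the default synthetic cohorts, similar
across both standardization orders. The full-rank alternative has no such
bias (it equals the direct regression, as tested) but is unusable here:
with all 489+ columns the MLE diverges under quasi-separation. The
reconstruction is therefore reliable for *ranking* influential variables
and families, not for unbiased per-column effect sizes, and the recovery
experiment's HDI-coverage outcome reported by `scripts/acceptance.py`
quantifies exactly this: injected effects rank at the top, but their
individual 99% HDIs sit near the projected (shrunk) values rather than the
raw truth.

## Numerical choices

- Log-likelihoods use logaddexp; no overflow for |η| up to ~700.
- Largest-remainder rounding fixes split sizes deterministically (ties to
  the earlier split), e.g. 17,366 → 8,683/4,342/4,341.
- HDIs are the shortest window of sorted draws containing ⌈mass·S⌉ draws.
- Split-R̂ (chains halved before the between/within comparison) is used —
  slightly more conservative than the classical diagnostic; constant
  identical chains define R̂ = 1.
- All randomness flows through explicitly seeded numpy Generators; stage
  seeds are derived from one run seed via SeedSequence.
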