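# Methods

## The question

An established marker X predicts a binary outcome y; a candidate marker X*
is proposed. Its incremental value can be tested inside the regression
model (likelihood ratio or Wald test of β₂ = 0 in
logit P(y=1) = β₀ + β₁X + β₂X*) or by comparing the discrimination of the
two models (DeLong's paired test of the AUCs of the in-sample linear
predictors ẑ). `nestedroc` implements all three and measures their
operating characteristics by simulation. The AUC comparison deliberately
reuses the fitted, non-cross-validated predictors: that is the common
applied practice whose consequences are being measured, not an oversight.
In-sample predictors make both estimated ROC curves optimistically biased,
and the bias is strongly correlated between the nested models, which is
the mechanism behind the AUC test's extreme conservatism.

## Generative model

For each of n subjects:

1. y ~ Bernoulli(π) (y = 1 when a U(0,1) draw falls below π);
2. X = μ·y + ε₁, ε₁ ~ N(0, 1);
3. X* = μ*·y + ρ·X + √(1−ρ²)·ε₂, ε₂ ~ N(0, 1).

With ρ = 0 this is the independent scheme: X* | y=1 ~ N(μ*, 1). With
ρ ≠ 0 both markers have unit unconditional variance and within-class
correlation ρ. Note the *literal* conditional recipe is used: among
subjects with y = 1 the marginal mean of X* is μ* + ρμ, not μ*. A
mean-centred alternative (X* = μ*·y + ρ(X − μ·y) + √(1−ρ²)·ε₂), which
keeps the class mean at μ* for every ρ, is available via `center=True` /
`--center`; the two coincide whenever μ = 0 or ρ = 0, which covers every
headline cell. The variance of the conditional draw is 1 − ρ²: any other
value would break unit unconditional variance.

Because the two class-conditional marker densities are normal with equal
variance, Bayes' rule gives an exactly logistic regression of y on X:

    logit P(y=1|x) = [logit(π) − μ²/2] + μ·x,

i.e. β₁ = μ and β₀ = −μ²/2 + logit(π). The sign of the quadratic term is
negative — expanding log{π·φ(x−μ) / [(1−π)·φ(x)]} leaves −μ²/2 — and the
parameter-recovery test (n = 10⁶ ML fit within 3 SE of these values)
pins it down empirically as well. `true_coefficients` returns this pair.

### Defaults

| parameter | default | meaning |
| --- | --- | --- |
| n | 500 | subjects per replicate |
| π | 0.5 | outcome prevalence (first-class parameter; 0.2, 0.05 sweeps supported) |
| μ, μ* | grid {0, 0.1, 0.2, 0.3} | class mean shifts ≈ weak-to-moderate effects (AUC of a single marker = Φ(μ/√2) ≤ 0.58) |
| ρ | grid {0, 0.1, 0.3, 0.5} | marker correlation |
| replicates | 2000 | per cell; binomial SE of a rate r is √(r(1−r)/2000) ≤ 0.011 |
| α | 0.05 | two-sided level, strict rejection p < α |

### Seeding and degenerate draws

Each replicate's stream is derived from a `SeedSequence` over (master
seed, n, π, μ, μ*, ρ, replicate index, attempt), so cells and replicates
are independent, reproducible in isolation, and order-independent —
results cannot depend on how a grid run is scheduled. A draw in which all
subjects share one outcome (probability (1−π)ⁿ + πⁿ, negligible at the
defaults but common at extremes like n = 12, π = 0.05) admits no logistic
MLE; it is discarded, the attempt counter incremented, and a fresh stream
drawn. The same policy covers replicates whose fit fails (separation);
discards are counted and reported per cell, and the denominator of every
rejection rate stays at the requested replicate count.

## Estimation

Both models are fitted by maximum likelihood with Newton-Raphson on the
Bernoulli log-likelihood written in the overflow-safe form
Σ yη − log(1+e^η). Step-halving guards the rare non-concave step; the
iteration stops when the score's infinity norm falls below 1e−8 (a
relative log-likelihood stall below 1e−15 is treated as converged, and 100
iterations, a non-finite likelihood, or any |β̂| > 40 — the signature of
separation — mark the fit failed). Stopping on the score rather than the
likelihood keeps the fitted probabilities' mean within 1e−8 of the sample
prevalence, an identity the tests assert. The covariance is the inverse
observed information at the optimum; the Wald test uses this model-based
standard error (not a sandwich estimator), matching default logistic
output.

The fitter is batched: a Monte-Carlo cell stacks all replicates into an
(R, n, p) design and iterates them together, freezing each replicate as it
converges so its Newton trajectory is bit-identical to a standalone fit.
This is purely a throughput device (one 2000-replicate cell ≈ 5 s on one
CPU); the statsmodels MLE is used in the test suite as an independent
check of coefficients, standard errors and log-likelihoods.

## The three tests

* **LRT**: G = 2(ℓ_expanded − ℓ_restricted), clipped at zero (solver
  noise), upper tail of χ²₁.
* **Wald**: z = β̂₂/se(β̂₂), two-sided standard normal.
* **DeLong paired AUC**: AUCs of ẑ_restricted and ẑ_expanded estimated by
  the Mann-Whitney statistic (ties credited ½ — measure-zero for the
  generator but defined for floating-point ties); for each positive
  subject its placement (tie-adjusted fraction of negatives it outscores)
  and symmetrically for negatives, computed from midranks in O(n log n);
  covariance of the two AUCs S₁₀/n₁ + S₀₁/n₀ from the placement sample
  covariances; z = ΔAUC/√var, two-sided normal, no continuity correction.
  If var(ΔAUC) < 1e−12 — e.g. the two predictors order subjects
  identically, which happens when β̂₂ is tiny — the comparison is flagged
  degenerate and p = 1 by convention (never a division by zero). Under
  strict rejection such replicates can never reject, which is consistent
  with reading "identical orderings" as no evidence of a difference.

A cell reports, per test, the fraction of replicates with p < α and its
binomial standard error.

## Validation strategy

Every component has an independent oracle in the test suite: AUC against
brute-force pair counting and sklearn's trapezoidal ROC area; the DeLong
variance against an explicit pair-matrix implementation, a stratified
paired bootstrap (200 datasets, 2000 resamples), and — for a single AUC —
the exact binormal sampling variance, whose Q₁/Q₂ terms are
bivariate-normal orthant probabilities with correlation ½; the logistic
MLE against a saturated 2×2 table's closed-form log odds ratio and
statsmodels; χ²/normal p-values against standard quantiles; null LRT
p-values against Uniform(0,1) by Kolmogorov-Smirnov; and the generator
against its own analytic coefficients.

## What the simulation does and does not show

The generator reproduces the idealised study conditions exactly: normal,
homoscedastic, unit-variance markers; a correctly specified logistic
model; no missingness, measurement error, censoring, covariates, or model
selection. Conclusions about the *relative* behaviour of the three tests
under these conditions are sharp; the absolute rates say nothing about
misspecified or messier real data, about cross-validated or externally
validated predictors (where the AUC comparison is a different procedure),
or about survival-type outcomes. One established marker only; non-normal
marker laws are out of scope.

## Numerical and design choices

* Rejection is strict (p < α); at α = 1 a degenerate-DeLong replicate
  (p = 1) therefore does not reject.
* Rates are compared across runs with a two-run band: 3 binomial SEs for
  each estimate, both runs carrying the same Monte-Carlo noise.
* The wide results table mirrors the usual presentation (rows μ*, μ,
  test; one column per ρ); the long CSV round-trips every rate bit-exactly
  (`%.17g` + round-trip parsing).
* Problem sizes in the shipped tests: full-size cells (2000 replicates,
  n = 500) for the reproduction tests, shared as session fixtures; reduced
  cells (100 replicates, n = 100) where only structure, determinism or
  serialization is at stake.
* The π = 0.5 base case follows the generation scheme's own statement;
  prevalence stays a first-class parameter so low-prevalence sweeps
  (0.2, 0.05) and n = 100 can be run with one flag.
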