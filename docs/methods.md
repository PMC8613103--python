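# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `glmsim`, and what the synthetic-data design does and does not show
about real data.

## The question and the simulation design

The reference analysis is simple linear regression, `Y_i = a + b·X_i + e_i`,
whose F test assumes Gaussian errors. The package measures what happens to
that test — and to Poisson/binomial/quasi-Poisson GLMs and random-intercept
mixed models — when the distributional assumptions are violated severely.
Both the response *and the predictor* distribution matter: the damaging
configuration is an outlier in X coinciding with an outlier in Y (a
high-leverage, high-influence point), which is why the benchmark set spans
the outlier-propensity spectrum.

### The ten benchmark marginals

| id | family | parameters | character |
|----|--------|------------|-----------|
| D0 | Gaussian | μ=0, σ=1 | reference |
| D1 | Bernoulli | p=0.5 | discrete, platykurtic (kurtosis 1) |
| D2 | Gaussian, categorized + zero-inflated | μ=3, σ=1, 5 categories, 50% zeros | discrete, zero-inflated |
| D3 | Gaussian, zero-inflated | μ=3, σ=1, 50% zeros | point mass at 0 |
| D4 | half-normal | σ=1 | skew 1.0 |
| D5 | Student's t | df=4 | heavy tails, infinite kurtosis |
| D6 | gamma, categorized | shape 1, scale 10, 3 categories | discrete, skewed |
| D7 | gamma–Poisson | shape 1, scale 10 | overdispersed counts (mean 10, var 110) |
| D8 | Bernoulli | p=0.9 | skew −2.67, rare minority class |
| D9 | gamma | shape 0.1, scale 100 | extreme skew (6.32), extreme outliers |

Post-processing order is base draw → categorization → zero-inflation, with
zeros *replacing* values. Categorization maps a draw to 1..K through
equal-probability bins of the base distribution (the original study does not
state its binning rule; this one is isolated in a single function so an
alternative can be swapped in — a consequence is that the published
skewness/kurtosis for D6, and the claim that effects cannot be induced on D6,
are not reproducible and are not asserted anywhere).

`analytic_moments` returns closed forms where they exist (Gaussian,
Bernoulli, gamma, gamma–Poisson via the negative-binomial identities,
Student's t with the infinite-kurtosis flag at df ≤ 4, half-normal, Poisson)
and falls back to a flagged large-sample estimate otherwise. Kurtosis is
reported non-excess (Gaussian = 3). `empirical_moments` uses the plain
moment estimators m₃/m₂^{3/2} and m₄/m₂² without small-sample corrections,
matching the convention of the moments estimators used for the published
table.

### Outlier tendency

A distribution's propensity to produce influential points is scored by
regressing a Gaussian response on n = 10 draws from the distribution and
averaging the fraction of points with Cook's D > 4/(n−2) over replicates.
Points with leverage exactly 1 (a Bernoulli(0.9) predictor produces them in a
third of N = 10 samples) have an undefined Cook's distance; the score treats
them as non-exceeding, which matches how R's `cooks.distance` (NaN) behaves
in the original tooling and keeps D9 — not D8 — the most outlier-prone
distribution, consistent with the published ordering. Note the score does
*not* reproduce a strictly increasing D0 < D1 < … < D9 ordering under any
convention we examined; the robust facts (D9 maximal; D1–D3 and D8 below D0)
are what the tests assert. The *diagnostics module* uses the opposite
convention for its screening proportions (h = 1 counted as exceeding), since
there the question is "should this point be flagged?", and a perfect-leverage
point should.

## Inducing an effect between arbitrary marginals

A target Pearson correlation r is induced by a Gaussian copula with rank
matching: draw a bivariate standard normal with intermediate correlation ρ*,
then replace each coordinate by the equally-ranked value of a fresh sorted
draw from its marginal. The output is a permutation of exact marginal draws,
so marginals are preserved exactly; the realized correlation is a distorted
function of ρ*, so ρ* is calibrated by additive feedback
(ρ ← ρ + (r_target − r̂), clamped to [−1, 1]), keeping the best ρ seen and
stopping at |r̂ − r_target| ≤ tol.

Two details matter in practice:

* **Calibration at the replicate sample size.** Rank matching within a
  replicate of size n attenuates the realized correlation (at n = 10 the
  attenuation is large: a ρ* of 0.70 is needed to realize a mean sample r of
  0.59). The calibration therefore measures r̂ as the *mean sample
  correlation over many rank-matched replicates of size n* — the same
  estimand the power grids report — so the long-run mean replicate
  correlation equals the target. Passing `n=None` instead calibrates on one
  large sample (there ρ* → r for Gaussian marginals).
* **Monte-Carlo error vs. tolerance.** Defaults are tol = 0.001,
  max_iter = 30, calib_n = 200,000 per iteration, with at least
  min(5000, calib_n/10) replicates per iteration so the standard error of r̂
  stays near the tolerance even at n = 1000. With fewer replicates the
  accepted ρ* is systematically biased toward the stopping band's near edge,
  which visibly biases power at small effect sizes.

Unreachable targets are a real phenomenon, not an error: the Fréchet bounds
of a Bernoulli(0.9)/gamma(0.1) pair cap the attainable correlation near 0.105,
so a target of 0.19 returns `converged=False` and the grids skip the cell
with an explanatory row. Zero targets short-circuit to ρ* = 0 exactly.

## Model fitting and nested significance

* Gaussian linear models: QR-based least squares; the error-variance
  estimate is unbiased (RSS/(n−k−1)); the log-likelihood uses the ML variance.
* GLMs (Poisson/log, Bernoulli/logit, Gaussian/identity) are fitted by
  statsmodels IRLS. Quasi-Poisson is the same fit with dispersion estimated
  as Pearson χ²/df; it has no likelihood.
* Gaussian random-intercept models are fitted by **maximum likelihood, not
  REML**, through statsmodels MixedLM, so likelihood-ratio tests between
  nested fixed-effect structures are valid. The LRT always retains the
  random effect in both models.
* The Poisson random-intercept/OLRE GLMM is fitted by our own adaptive
  Gauss–Hermite maximum likelihood (25 nodes, integrand mode and curvature
  per group by Newton steps; the one-node case is the Laplace approximation).
  It reproduces lme4's `glmer(nAGQ=25)` coefficients, variance and LRT
  statistic to ~1e-3 on frozen reference datasets. The OLRE (one intercept
  per observation, i.e. a Poisson-lognormal model) absorbs extra-Poisson
  dispersion; its variance estimate sits at the boundary (≈0) for
  equidispersed data, which is recorded, never dropped.

Nested significance follows the study's rule — an exact F test wherever one
exists, a likelihood ratio test otherwise: Gaussian fixed-effect fits get the
RSS F test (identical to the square-of-t test for one slope), quasi-Poisson
gets the deviance-difference F test scaled by the full model's Pearson
dispersion against F(Δdf, df_resid), and Poisson/binomial GLMs and all mixed
models get the χ² LRT.

### Batch engines

Grids run tens of thousands of replicates per cell, so the simple-regression
special cases are vectorized across replicates: the closed-form correlation
F test; a batched Newton solver for single-predictor Poisson and logistic
GLMs (null fits are closed-form); batched normal-equation OLS for the
multi-predictor F test; and an exact profiled-ML solver for the balanced
paired random-intercept model (the pair-sum/pair-difference transform makes
β and σ² profile out in closed form, leaving a one-dimensional likelihood in
the variance ratio that golden-section search maximizes, with the σ_u² = 0
boundary checked explicitly). Every batch path is tested against the
per-dataset statsmodels/OLS route; the paired solver matches lme4's ML LRT
to 1e-6. The OLRE GLMM does not vectorize and is fitted per replicate.

### Degenerate replicates

At N = 10 a Bernoulli(0.9) variable is constant in ~35% of samples; a
constant predictor or a zero-residual response leaves the F statistic
undefined. Such replicates are dropped and counted, and reported per cell
(`n_failed`); a cell aborts with a reason row if more than half its
replicates fail (both variables Bernoulli(0.9) at N = 10 is the one standard
cell this triggers for). This is a deliberate policy choice: fitting software
will happily emit a floating-point-noise F statistic for a constant response,
and those artifacts can dominate a cell's apparent type-I error rate.

## Metrics

Rejection rates carry binomial standard errors √(p̂(1−p̂)/m). The scale shift
υ is the SD of observed −log₁₀(p) over the SD of −log₁₀ of the plotting
positions i/(m+1) (beta-distribution means; υ is insensitive to the
plotting-position convention under the null). Tail fold-bias at expected
exponent e is −log₁₀(empirical 10⁻ᵉ quantile of p)/e, using type-7 quantiles;
at e = 4 and 50,000 replicates the estimate rests on ~5 order statistics and
swings by ±0.5 across seeds, so the package's own reproduction runs use
150,000 replicates. Concentration bands for the i-th ordered p-value are
central quantiles of Beta(i, m+1−i). Slope bias/precision are the mean and
CV of replicate slopes; the CV is flagged unstable when the mean is within
3 SE of zero. Clopper–Pearson intervals come from beta quantiles and are
central two-sided at level 0.95 by default. The required effect for a target
power inverts the noncentral-t power function (df = n−2, noncentrality
δ = r√n/√(1−r²)) by bisection; far-tail noncentral-t underflow is clamped
to zero.

## Grids, seeding, output

Each cell derives its generator from a 31-bit BLAKE2 hash of (grid name,
distribution labels, n, model, target r) combined with the base seed:
reproducible under any execution order, embarrassingly parallel
(`n_jobs`/`--jobs` via joblib), byte-identical CSV output for identical
configuration and seed. Replicates are processed in blocks capped at 5·10⁶
matrix elements to bound memory.

The LMM grid pairs 100 groups × 2 observations; the response is a
per-replicate standardized draw from the Y distribution plus a Gaussian group
intercept with variance icc/(1−icc) (default icc = 0.3, i.e. the random
effect carries 30% of the response variance; the realized marginal of Y is
then a convolution of the target distribution with a Gaussian — the target
marginal itself is not preserved). The multivariate grid adds the focal
predictor to three independent standard-normal covariates at N = 100. The
family-comparison grid has a null ("misspecification") mode pooling each
discrete response's p-values across the ten predictor distributions, and a
"power_comparison" mode that couples a raw-scale count/binary response to a
standardized predictor at target r = 0.2 (chosen to give ≈50% power at
N = 100) and fits both a Gaussian model and the distribution-matched GLM; the
back-transformed "effect" column is the inverse link of (intercept + slope),
i.e. the predicted mean one predictor SD above average.

Default replicate counts follow the original design (50,000 per cell); all
reproduction runs in the test suite and acceptance script state their reduced
sizes explicitly (5,000–150,000 depending on the quantity's order-statistic
depth), chosen so the Monte-Carlo error is small against each quantity's
tolerance.

## What the synthetic design does not show

* Data are i.i.d. within a replicate: no heteroscedasticity, autocorrelation,
  cluster structure beyond the single random intercept, or collinearity.
  Robustness here says nothing about violating *independence*, which is a
  far more dangerous assumption to break.
* The rank-matching coupling induces a specific (Gaussian-copula) dependence
  shape; real bivariate dependence can be tail-heavy in ways this does not
  emulate.
* Power/bias conclusions are for the standardized-slope estimand; GLM
  coefficients on link scales are compared only descriptively.
* The categorization rule for D2/D6 is this package's documented choice;
  quantities that depend on its fine structure should not be compared
  against the original study's D6 values.
* The rankit (RIN) transform normalizes continuous shapes; discrete
  variables with few support points keep their point masses (a Bernoulli
  stays two-valued), so the "normalize then fit Gaussian" remedy only applies
  to continuous data.
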