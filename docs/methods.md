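# Methods

This note records the statistical model, the estimation algorithm, the
design decisions that were genuinely open, and what the synthetic-data
experiments do and do not establish.

## Outcome distribution

All phenotypes are strictly positive, right-skewed, and change their
spread (and skew) with age, so the outcome family is the three-parameter
generalized gamma in the parameterization

    theta = 1 / (sigma^2 nu^2),  z = (y / mu)^nu
    f(y)  = |nu| theta^theta z^theta exp(-theta z) / (Gamma(theta) y)

chosen because it makes `mu` a natural-scale location (the log link then
gives exact scale equivariance), contains the gamma (`nu = 1`, shape
`1/sigma^2`, mean `mu`) and the log-normal (`nu -> 0`, parameters
`log mu, sigma`) as special cases, and is the standard form in the
distributional-regression literature. For `nu < 0` the power transform is
decreasing and the CDF uses the upper regularized incomplete gamma
`Q(theta, theta z)`; for `|nu| < 1e-5` every operation switches to the
log-normal limiting form, since `theta` diverges as `nu -> 0`. The
log-density is evaluated in the cancellation-free form
`log|nu| + C(theta) - theta*(expm1(u) - u) - log y` with
`C(theta) = theta log theta - theta - lgamma(theta)` (Stirling series for
`theta >= 1e8`), so the likelihood and its gradients stay accurate
arbitrarily close to the log-normal boundary. Sampling is inverse-CDF on
uniforms from a counter-based (Philox) generator, giving bit-identical
draws for a fixed seed on any platform.

Moments: `E[y^k] = mu^k theta^(-k/nu) Gamma(theta + k/nu) / Gamma(theta)`
exists only when `theta + k/nu > 0`; the between-subject SD curve reports
NaN at parameter settings where the second moment is undefined rather
than raising.

## Age convention

The internal age covariate is **years post-conception**
(`age_days / 365.25`), strictly positive so that logs and negative
fractional-polynomial powers are defined for foetal scans. Ages are
*reported* relative to birth using a 280-day (40-week) gestation
convention, so prenatal landmarks come out negative. The default floor is
80 days post-conception.

## Linear predictors and fractional polynomials

`log mu` and `log sigma` each get: an intercept; sex (one indicator,
female reference); optionally a processing-version one-hot (location
only); a fractional-polynomial age basis; and optionally a per-study
Gaussian random intercept. The shape `nu` is always a free intercept on
the identity link — higher-moment age trends demand far more data than
location/scale trends and are deliberately excluded. Fractional
polynomials use the standard power set {-2, -1, -0.5, 0, 0.5, 1, 2, 3},
power 0 denoting `log x`, and a power repeated k times contributing
`x^p, x^p log x, ..., x^p (log x)^(k-1)`; orders 0–3 with repetition give
1 + 8 + 36 + 120 = 165 candidate bases per moment. No smoothing terms,
interactions, random slopes or crossed random effects.

## Estimation

Penalized maximum likelihood with cyclic per-moment block updates:

1. maximize over `[beta_mu, gamma_mu]` (L-BFGS with analytic gradients;
   random intercepts are coefficients with ridge penalty
   `sum(gamma^2) / (2 delta2)`), then re-center the `gamma` into the
   intercept (this never decreases the penalized objective);
2. the same for `[beta_sigma, gamma_sigma]`;
3. a bounded 1-D search for `nu` in [-5, 5];
4. a Schall-type fixed-point update of each random-effect variance,
   `delta2 = sum(gamma_j^2) / sum(h_j)` with leverage
   `h_j = S_j delta2 / (S_j delta2 + 1)`, where `S_j` is study *j*'s
   summed expected information (per-observation weights `1/sigma^2` on
   the location link and `4 theta^2 (psi'(theta) - 1/theta)` on the
   scale link — the exact Fisher weights of this family).

The outer loop stops when the relative change of the penalized
log-likelihood drops below `tol` (default 1e-6, max 200 cycles);
non-convergence is flagged on the result, not raised. Starting values are
scale-aware and deterministic: `beta_mu0 = log median(y)`,
`beta_sigma0 = log(1.4826 * MAD(log y))`, `nu = 1`, everything else 0.
The whole fit is deterministic, so refits are bit-identical. Standard
errors come from the expected information of the joint
`[beta, gamma]` block at convergence with the variance treated as fixed;
the bootstrap (participant resampling stratified by study and sex) is the
primary CI mechanism. The reported `loglik` is the unpenalized
log-likelihood at the fitted parameters (random effects at their
posterior modes) and `BIC = -2 loglik + n_params log(n_obs)` counts fixed
effects, the shape intercept, and one variance per active random term.

**Model selection** is a staged BIC search: all candidate location power
multisets with the scale intercept-only, then scale powers given the best
location basis. Ties within 1e-9 break toward fewer parameters, then
lexicographic powers; candidates that fail to converge rank last. This
staged search is this package's own protocol — a pragmatic stand-in for
the selection machinery used in the original growth-chart literature,
which is not reproduced here.

## Centile scoring and out-of-sample alignment

A scan's centile is the fitted CDF at its observed value, clamped into
[1e-6, 1 - 1e-6] to keep downstream probit transforms finite. Prediction
modes: *population* (random effects zero), *known-study* (add the fitted
study intercepts), or *offset* (add supplied link-scale shifts). For a
new study the offsets `(d_mu, d_sigma, d_nu)` are estimated by plain
maximum likelihood with all population parameters frozen — no shrinkage
toward zero by default (an optional ridge weighted by the fitted
random-effect variances exists behind a flag). `d_nu` is estimated by
default but bounded to |d_nu| <= 2 to prevent degeneracy on small
studies; studies with fewer than 100 scans carry a `small_sample_warning`,
reflecting the stability threshold established for this class of
out-of-sample alignment. Useful error propagation: the ML estimator of
`d_sigma` has SE ≈ `1/sqrt(2n)` (≈ 0.032 at n = 500), which is why
recovery checks at the ±0.02 level aggregate several replicate studies
(median of 9) and why the recovery experiments freeze the *true*
generating chart as the population model — against a finite fitted
reference, the reference's own population-intercept error (SD ≈
`delta_mu / sqrt(n_studies)`) dominates the comparison.

## Trajectories, variability, milestones

Centile curves evaluate the quantile function on an age grid
(population mode by default); the between-subject variability curve is
the analytic SD of the outcome distribution, with percentile bands from
≥ 20 bootstrap refits. Velocity is the first derivative of a sampled
median curve: central differences in the interior, one-sided at the
ends, on a daily grid (`h = 1/365.25` years — resolution well below the
width of any bootstrap CI of interest). Milestones are grid argmaxima of
the median curve (peak) and of its velocity; headline milestones average
the female and male median curves pointwise before the argmax, with
per-sex landmarks also reported. A monotone curve returns the endpoint
with an `interior` flag set to False rather than raising. The grey/white
differentiation epoch is the first sign change of the difference of two
median curves (direction recorded, so swapping arguments flips it)
followed by the argmax of their absolute difference at or after the
crossing. Bootstrap CIs for milestone ages are 2.5/97.5 percentiles over
replicates, excluding (and counting) replicates whose maximum fell on a
grid endpoint.

## Cohort statistics

* **Centile Mahalanobis distance (CMD).** The control group's centile
  matrix defines a mean vector and principal axes (eigendecomposition of
  the covariance, axes ordered by variance, sign fixed
  largest-loading-positive, near-zero-variance axes dropped with a
  warning). A subject's CMD is the sum over axes of
  |projection| / axis-SD — the absolute-sum reading of "sum of distances
  on all dimensions"; the classical Euclidean Mahalanobis form is
  available behind a flag since the exact normalization is a genuinely
  open choice.
* **Case–control tests.** Pairwise two-sided Monte Carlo permutation
  tests on the difference of group medians,
  `p = (1 + #{|T*| >= |T|}) / (1 + n_perm)`, Benjamini–Hochberg FDR
  across pairs within a phenotype × sex stratum, Cohen's d from the
  pooled SD, and an omnibus Welch-type F on centiles with a 500-resample
  within-group bootstrap null (groups centred to impose the null). The
  omnibus construction is this package's documented stand-in for a
  "bootstrapped non-parametric generalization" of Welch's ANOVA, which
  has no canonical definition.
* **Longitudinal stability.** Per-subject IQR of centiles across
  timepoints, `Q3 - Q1` with linear-interpolation quantiles (the default
  of mainstream statistical environments, fixed here for
  reproducibility); subjects with one session are excluded and counted.
* **Twin heritability.** Falconer's `h2 = clamp(2 (r_MZ - r_DZ), 0, 1)`
  on double-entered (intraclass-style) Pearson pair correlations, CI by
  pair bootstrap. This is deliberately the simple estimator: a full ACE
  variance-components model is out of scope. Heritability analyses should
  use *centile* pairs — raw phenotype pairs share the within-pair sex
  effect, which inflates both correlations and biases `h2` downward
  (≈ 0.54 instead of 0.60 for the GMV-like preset).

## Synthetic cohorts: what they emulate, and what they don't

The generator draws ages log-uniformly over the lifespan (dense early
life, sparse late life, as in aggregated multi-study MRI collections),
unequal study sizes on request, Bernoulli sex, per-study Gaussian
intercepts on both links, and outcomes from the exact generalized gamma
of a known `TrueModel`. Presets (`gmv_like`, `wmv_like`, `ct_like`) are
log-quadratic in log-age — a second-order fractional polynomial with the
repeated power 0 — because that shape guarantees a single interior peak
with monotone decline after it, makes the selection-consistency truth
unambiguous, and has closed-form peak and velocity-peak ages for use as
analytic oracles. Their magnitudes are realistic (e.g. the GMV-like
median peaks at ≈ 7.6 × 10⁵ mm³ at 5.9 years after birth, CV ≈ 12%,
study-intercept SD 0.08 ≈ 8% between-study spread) but they are
*fixtures*, not estimates of any real cohort. Clinical groups shift the
location predictor by the amount that moves the median subject to a
target centile (inverting the outcome CDF); longitudinal subjects keep a
latent normative rank with a configurable drift per year plus small
probit-scale jitter; twin pairs are bivariate-normal liabilities with
correlations `a2 + c2` (MZ) and `a2/2 + c2` (DZ).

Passing tests on these cohorts establish that the estimation, scoring,
offset, milestone and inference machinery is correct *under the model's
own assumptions*. They do not establish robustness to real-data features
the generator omits: image-quality artefacts, non-gamma outliers,
age-by-study confounding, scanner upgrades within a study, diagnostic
heterogeneity, or ascertainment bias.

## Numerical choices and problem sizes

Exponent arguments in the likelihood are clipped at ±200 (reachable only
at wildly wrong line-search trial points), non-finite block objectives
are mapped to a large finite penalty, and `nu` is box-bounded in [-5, 5].
The simulation studies run at deliberately moderate sizes — a 20-study ×
200-scan reference cohort for recovery and calibration, n = 5000 over 20
replicates for selection consistency, 151 replicate studies per size for
the out-of-sample bias curve, 1000 null repetitions at 199 permutations
for test calibration — chosen so that each check's Monte Carlo error is
small relative to its tolerance while the whole suite stays fast.

## Known limitations

Cross-sectional model only (longitudinal correlation enters solely
through the stability metric); no kurtosis parameter; no censoring or
truncation; BIC-staged search explores location and scale bases
sequentially, not jointly; expected-information SEs ignore variance-
estimation uncertainty (use the bootstrap for serious intervals); the
shape `nu` is weakly identified at realistic sample sizes (its profile
likelihood is nearly flat over wide ranges), which is harmless for
centiles — location/scale compensate — but means `alpha_nu_` itself
should not be over-interpreted.
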