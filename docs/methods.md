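# Methods

## Model and estimation

The package models the τ-th conditional quantile of under-five BMI as
x′β(τ) and estimates β(τ) by Bayesian inference under the asymmetric
Laplace (ALD) working likelihood. The ALD density used throughout is the
check-loss exponential form

    f(y | μ, σ, τ) = τ(1−τ)/σ · exp(−ρ_τ((y−μ)/σ)),

whose τ-quantile is exactly μ; this is the unique density for which
maximizing the likelihood in μ is the same problem as minimizing the summed
check loss. The error scale is fixed at σ = 1 in the default sampler: the
exponential–normal mixture representation the Gibbs sampler is built on
carries no free scale, and the regression coefficients — the quantities of
interest — are invariant to how the working spread is handled. An optional
third Gibbs block (`estimate_scale=True`) places an inverse-gamma prior on
σ (shape 0.01, rate 0.01) and updates it from its conjugate full
conditional; it is off by default and changes interval widths, not point
estimates, in well-behaved problems.

### Full conditionals

With latents l and mixture constants γ, h as in the README:

* β | y, l ~ N(m, V) with V⁻¹ = Ω₀⁻¹ + Σ xᵢxᵢ′/(h²lᵢ) and
  m = V(Ω₀⁻¹β₀ + Σ xᵢ(yᵢ − γlᵢ)/(h²lᵢ)).
* lᵢ | y, β ~ GIG(1/2, |rᵢ|/h, √(γ²/h² + 2)), rᵢ the residual. A GIG of
  order 1/2 is sampled exactly as the reciprocal of an inverse-Gaussian
  draw (numpy's `Generator.wald`, the transformation-with-root-selection
  method); the scheme is rejection-free and specialized to the single
  order the sampler needs.

### Numerical choices

* The Gaussian block is drawn through a lower-Cholesky factorization of the
  precision matrix (solve, never an explicit inverse); a factorization
  failure raises with a collinearity diagnostic instead of regularizing
  silently.
* Residuals below 1e-10 in magnitude are floored before forming the GIG
  parameters: a = 0 would make the order-1/2 draw improper. The floor is
  far below any data scale and has no measurable effect on the chain.
* Initialization: coefficients at the least-squares solution, latents at 1.
  The least-squares start is deterministic and shortens burn-in; the chain
  forgets it well within the default 1,000-iteration burn-in.
* Priors default to β₀ = 0, Ω₀ = 100·I, a diffuse choice on the kg/m² scale
  of BMI coefficients; both are user-overridable per fit.
* Schedule defaults: 10,000 iterations, 1,000 burn-in, thinning 5, hence
  ⌊(10000−1000)/5⌋ = 1,800 retained draws per level.
* Multi-quantile runs derive one seed per level from the master seed via
  `SeedSequence([master_seed, level_index])` (first state word, reduced
  mod 2³¹), so each chain is independently reproducible.
* The frequentist cross-check (`check_loss_minimizer`) minimizes the
  non-differentiable check-loss objective with derivative-free Powell
  search restarted from its own solution until the objective stops
  improving; the loss surface is piecewise linear and a single pass can
  stall on a ridge. It exists to validate the sampler, not to replace it.

## Summaries and diagnostics

Credible intervals are equal-tailed empirical quantiles of the retained
draws (not HPD), matching the symmetric presentation conventional for
multi-quantile coefficient tables; significance means the 95% interval
excludes zero. A constant chain is rejected rather than reported with a
degenerate interval. Convergence is assessed visually — trace, marginal
density (Gaussian kernel, Scott's rule bandwidth) and autocorrelation
exports per coefficient and level — plus an advisory numeric heuristic
(lag-1 autocorrelation and a split-chain mean gap) that never gates the
pipeline. Autocorrelation uses the standard biased estimator with
overall-mean centering, so the lag-0 value is exactly 1.

## Descriptive layer

BMI is raw weight/height² in kg/m²; no age- or sex-standardization is
applied, consistent with classifying children against *within-sample*
percentiles rather than external growth references. Percentiles use
sorted-order linear interpolation (the "type 7" rule, the dominant software
default, under which the median of 1..100 is 50.5). Weight status is
underweight below the sample 5th percentile, normal from the 5th up to the
85th, overweight from the 85th up to the 95th, and obese at or above the
95th; the upper class is closed on the left at every boundary, so the rule
partitions any sample exactly. Frequency-table percentages are rounded
half-up to one decimal, the convention under which the reference survey's
printed categorical table reproduces exactly from its counts.

## Synthetic data generator

The generator emulates the structure of a 2019 Ethiopian mini-DHS child
file: 5,323 children by default, child age discrete-uniform on 0–59 months,
maternal age discrete-uniform on 15–49 years, and thirteen categorical
covariates drawn with the survey's published marginal proportions (region
shares are not published in that table; plausible round values summing to 1
are used instead and are a modeling choice). Reference categories for
dummy coding follow the usual reporting convention (male, urban, Tigray,
Orthodox, poorest, no formal education, ever-breastfed, ≤4 household
members, <2 under-fives, singleton, improved water, improved toilet).

The outcome is a location-scale model y = Xβ_loc + (Xβ_scale)·z with z
standard normal or centered ALD, so the true τ-level coefficient vector is
available in closed form (β_loc + β_scale·Φ⁻¹(τ) for gaussian noise; β_loc
at the ALD's own level). The default truth puts the median BMI near
15.3 kg/m² with a −0.02 kg/m² per month age effect and a mild positive
scale dependence on age, so true quantile slopes fan out with τ. ALD-noise
fixtures standardize the noise to a 1.5 kg/m² standard deviation
(σ_τ = 1.5/√(γ²+h²)): the survey-scale BMI percentile span (5th ≈ 12.9 to
95th ≈ 18.3) corresponds to a spread of roughly 1.5–1.6 kg/m², whereas a
unit-scale ALD at tail levels would have a standard deviation near
20 kg/m², far outside anything anthropometric.

What the generator does **not** emulate: dependence among covariates (no
wealth-region or education-residence association — the regression
conditions on X, so independence does not bias correctness testing but
does make the synthetic tables unrealistically orthogonal), the two-stage
cluster sampling design and its weights, spatial autocorrelation, and
age-by-sex growth-curve structure in BMI. Passing recovery tests therefore
demonstrates that the sampler estimates what it claims under the stated
data-generating law; it does not validate substantive conclusions about
any real survey.

## Problem sizes used in the checks

The bundled verification runs use n = 200 (p = 3) for the
sampler-vs-minimizer agreement at all six default levels, n = 2,000
fixtures with the full 10,000/1,000/5 schedule for coefficient recovery
(compact four-column design: intercept, child age, sex, residence), 10⁴
draws per level for the two-sample distributional checks, 10⁵ draws for
sampler moments and the weight-status partition, and 50 replicates at
n = 500 with a shortened 2,000/500/2 schedule for interval-coverage
calibration; these sizes give Monte-Carlo error comfortably below each
check's tolerance. Coverage is checked at the median with ALD noise at the
fitted level and unit scale, where the fixed-scale working likelihood is
exactly the data law and nominal coverage is the theoretically expected
outcome; with misspecified noise, ALD-based posterior intervals are known
to need sandwich-type corrections that are outside this package's scope.

## Known limitations

* Fixed σ = 1 means interval widths are trusted only when the residual
  scale is comparable to 1 or the scale block is enabled.
* Single-chain diagnostics only; no Gelman–Rubin statistic or formal
  effective-sample-size estimator.
* No survey weights or design-based variance; the fit is an unweighted
  model of the supplied rows.
* The frequentist cross-check relies on a derivative-free minimizer and
  is accurate to roughly 10⁻² on flat check-loss ridges, which is ample
  for its validation role but not LP-exact.
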