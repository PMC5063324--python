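# Methods

## Model

Chlorophyll *a* is modelled on the log10 scale. For observation `t` at lake
location `s`,

    y_t(s) = x̃_t(s)ᵀ β̃(s) + x_t(s)ᵀ β + e_t(s),    e_t(s) ~ iid N(0, τ²),

with `x̃ = (1, log10 TP, log10 color)ᵀ`. The three coefficient surfaces are a
zero-distance-correlated multivariate Gaussian process,
`β̃(s) ~ MVGP(β̃_mu, Σ(θ))`, built by the Linear Model of Coregionalization:

    Σ(θ) = Σ_{j=1..3} (a_j a_jᵀ) ⊗ R_j,      R_j(d) = exp(−φ_j d),

where `a_j` is the j-th column of a lower-triangular coregionalization matrix
`A` (so `K = AAᵀ` is the among-coefficient covariance at distance zero) and
`φ_j` is a per-process decay rate in km⁻¹. Stacking is coefficient-major.
The effective spatial range of process j is the distance at which correlation
drops to 0.05: `−ln(0.05)/φ_j`.

Assumptions worth stating plainly: residuals are independent across lakes and
over repeat visits (no temporal structure); all repeat visits of a lake share
one coefficient vector `β̃(s)`; coefficient surfaces are stationary and
isotropic in planar km; the exponential family fixes the correlation shape
(the `CorrelationSpec` class is the extension point for Matérn, and any
effective-range comparison inherits the exponential assumption).

## Priors

The priors are weakly informative and scale-aware:

* `β̃_mu, β ~ N(0, 10⁴)` elementwise.
* `τ² ~ Inverse-Gamma(2, 0.1)`.
* `φ_j ~ Uniform(−ln .05 / d₉₅, −ln .05 / d₅)`, where `d₅`/`d₉₅` are the 5th
  and 95th percentiles of inter-site distance — i.e. effective ranges are
  a-priori confined to distances the site network can resolve.
* `diag(A) ~ half-Normal(1)`, off-diagonal `~ N(0, 1)`.

## Sampler

One Metropolis-within-Gibbs iteration:

1. `(β̃_mu, β)`: exact conditional Gaussian (conjugate), given the deviation
   fields and τ².
2. Stacked deviations `w = β̃(s) − β̃_mu`: joint conditional Gaussian with
   precision `Σ(θ)⁻¹ + data term`; the data term is the per-site Gram matrix
   of `x̃` over τ², so the no-data limit reverts to the MVGP prior.
3. `τ²`: Inverse-Gamma(shape + n/2, scale + SSR/2).
4. `θ`: two random-walk Metropolis blocks conditional on `w` — all three
   `log φ_j` jointly, then `A` (log-diagonal, raw off-diagonal) — with
   uniform-support auto-rejection and the appropriate log-scale Jacobians.

Internally the fields are parameterized as deviations with a zero-mean GP
prior; this is algebraically identical to the centered statement and makes
block 1 conjugate. Reported `site_coeffs` are always `β̃_mu + w(s)`.

Step sizes adapt by Robbins–Monro (`scale *= exp(t^-0.6 (acc − 0.35))`)
during burn-in only and are frozen afterwards, preserving ergodicity.
Defaults are 25,000 iterations, 15,000 burn-in, thinning 10; the examples,
tests and acceptance script use 3,000–6,000 iterations with half burn-in,
which split-chain R-hat (reported by `SVCResults.rhat`, via arviz) shows is
adequate at the 40–150-site problem sizes they run. Chains are fully
reproducible under a seed, and a non-finite log-density aborts with
diagnostics rather than silently continuing.

Numerical choices: covariance factorizations add a relative jitter of 1e-8 ×
mean diagonal; `Σ(θ)⁻¹` is computed once per accepted θ (LAPACK `dpotri`)
and cached; distinct lakes with identical coordinates are jittered by 0.001
km with a loud warning (coincident sites would make Σ singular); the
initial state is least squares for the mean parameters, zero fields, and the
geometric mid-point of the φ prior.

## Model comparison and prediction

DIC = D̄ + pD with pD = D̄ − D̂, where the plug-in deviance D̂ is evaluated
at the posterior means of the **full** parameter set, site-level coefficient
fields included. This conditional-focus convention makes pD of a spatial
model count the effective number of field degrees of freedom (hundreds),
which is what allows DIC to compare spatial and non-spatial candidates on one
scale. Holdout prediction is composition sampling: for each retained draw,
coefficients at unseen lakes are kriged from the GP conditional under that
draw's θ (reverting to β̃_mu with full marginal variance far from data), then
`y* ~ N(linear predictor, τ²)`. Scores: RMSPE of predictive means, CRPS
(closed form for Gaussian forecasts, order-statistics estimator for draws),
and equal-tailed 95% interval coverage (PCI) and width (PIW), all on the
log10 modelling scale.

## Data pipeline conventions

Inclusion rules: lake area strictly inside (4, 10 000) ha (boundary values
dropped); sampling date inside 15 June–15 September inclusive; CHL, TP and
color all present on the same (lake, date) record; maximum depth present.
Removals are attributed to the first failing rule in the order area →
season → triplet → depth; the kept set itself is order-invariant. Multiple
same-day samples of a lake are all kept. Holdout splits are by observation
(floor(fraction × n) rows withheld), so a multiply-sampled lake may appear
on both sides — matching how repeat-visit lakes behave under a random
observation split. Coordinates: planar km are used as-is; lon/lat are
projected with a spherical equidistant conic centred on the data bounding
box (standard parallels at the 1/6 and 5/6 latitude quantiles), accurate to
well under 1% against great-circle distances at a few-hundred-km extent.

## Synthetic data

`svclake.simulate` forward-simulates the model itself, so parameter-recovery
tests are exact by construction. Defaults are the study conditions: mean
coefficients (−0.36, 0.698, −0.02), τ² = 0.63, effective ranges
(32.56, 26.32, 216.05) km on a 300 × 300 km extent, log-normal TP and color
with median 14, maximum depth median 9.2 m, Dirichlet land-cover proportions,
72% drainage lakes, and a repeat structure in which ~27% of lakes receive
Poisson(29) extra samples — reproducing a population where most lakes are
sampled once but revisited lakes carry ~30 observations. The
coregionalization matrix (intercept/TP/color field scales 0.35/0.21/0.12
with mild intercept–TP correlation) is chosen once from the reported
across-lake spread of coefficient values. What the generator does **not**
emulate: the real lakes' geographic footprint, spatially structured
land-cover fields, covariate–covariate confounding (off by default), or
non-Gaussian residuals — so passing tests demonstrate correctness of the
machinery under the model's own assumptions, not robustness to their
violation.

## Problem sizes

The test suite and acceptance script scale the simulations to desk size as
the package's own verification design: parameter recovery uses 10 replicates
of 100 lakes (~900 observations, 6,000 iterations); the DIC comparison uses
80 lakes; predictive calibration uses 150 lakes with a 500-observation
holdout; the full-population split arithmetic uses 838 lakes / 7,395
observations without fitting. At these sizes the identification of the decay
parameters φ is genuinely weak — a single GP realization at ~100 sites
carries little information about range — so recovery checks on effective
ranges are order-of-magnitude (factor 2.5) while mean coefficients and τ²
are checked by interval coverage.

## Known limitations

* Dense covariance algebra: O((n_sites·3)³) per θ evaluation; practical to
  roughly a thousand lakes. Predictive-process or nearest-neighbour GP
  approximations are natural extensions.
* θ updates condition on the sampled fields rather than marginalizing them;
  simpler and cheaper, but mixing of (φ, A) is slower than a marginalized
  sampler would be.
* The φ posterior is prior-bounded to resolvable distances; truth outside
  those bounds (e.g. very long-range processes on a small extent) is
  recovered only up to the bound.
* IDW surfaces are presentation artifacts, deliberately not kriging; no
  uncertainty propagates to the maps.
* Pearson correlations of per-lake coefficients with covariates are reported
  unadjusted for multiplicity, with a log note.
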