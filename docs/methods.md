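# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `paleodispersal`, in the order the pipeline runs.

## Data model and preparation

The analysis table holds one radiocarbon determination per row: lab id,
site id, coordinates (decimal degrees, west negative), uncalibrated ¹⁴C age
`x` (BP) with 1σ error, and a binary ceramic-presence flag `y`. The
presence model is Bernoulli, so determinations with genuinely unknown
association are excluded at load time via an `unknown` marker — there is no
third state.

Screening keeps latitudes in [10, 34]°N and uncalibrated ages in
[7000, 12000] BP (closed intervals). The screening range is applied to
uncalibrated ages; the source protocol states a BP range without "cal" and
the choice only moves a handful of boundary dates.

To control for uneven sampling intensity between sites, same-site dates are
*binned*: agglomerative complete-linkage clustering on absolute ¹⁴C-age
differences, dendrogram cut at 100 years, so no bin spans more than the
threshold. One representative per bin is kept — the date with the smallest
measurement error, ties broken by a seeded uniform draw, so preparation is
reproducible. Distances to candidate origins are haversine great-circle
kilometres on a sphere of radius 6371.0088 km, stored unscaled.

Calibration curves are tabulated (cal BP, ¹⁴C BP, 1σ) triples read from the
five-column IntCal-style format; mean and error are interpolated linearly
and evaluation outside the tabulated support is an error, never an
extrapolation. The measurement model is

x_i ~ Normal(f(θ_i), σ_i),  σ_i² = (lab error)² + (curve error at θ_i)².

Calendar axes are cal BP everywhere (larger = older); intervals are written
(older bound, younger bound). Calibrated densities are discrete weights on
a regular integer grid (default 1-yr step), normalised to sum to one, so
probability masses are reproducible sums rather than quadratures.

## Dispersal-front quantile regression

For one candidate origin, presence-bearing dates are modelled with the
asymmetric Laplace (AL) likelihood whose maximum corresponds to check-loss
quantile regression at quantile τ:

θ_i ~ AsymLaplace(γ₀ + γ₁ d_i, λ, τ = 0.05)

The τ = 0.05 front tracks the *early edge* of the dated distribution. On
the cal BP axis the early edge is the upper tail, so the fit uses an
effective quantile 1 − τ; this is numerically identical to negating the
calendar axis and using τ, and the edge choice is configurable
(`tau_edge: early|late`). Under outward dispersal γ₁ is negative in cal yr
per km (arrival younger farther out); |1/γ₁| is the front speed in km/yr.

Priors (weakly informative; exact production priors were not published, so
these are this package's defaults): γ₀ ~ Normal(mean point-calibrated date,
2000 yr); γ₁ ~ Normal(0, 1 yr/km) — a 1σ slope of 1 yr/km corresponds to a
1 km/yr front, generous for Holocene technology spread; λ ~ Exponential
(mean 500 yr); θ_i uniform over the curve support. The slope prior is
placed directly on the km scale rather than after a covariate scaling step;
the quantile model has no other scaled covariates, and the two
parameterisations are equivalent.

## Single- and multi-origin binomial diffusion

Presence is a logistic function of (scaled, centred) calendar date and
distance:

y_i ~ Bernoulli(p_i),
logit(p_i) = β₀ − β_time θ_i − β_distance d_i + β_interaction d_i θ_i

with the signs exactly as printed above: with θ in scaled cal BP, positive
β_time means presence grows as time passes, positive β_distance means decay
away from the origin, and the interaction lets diffusion accelerate or
decelerate with distance and time. Multi-origin models give each origin a
*full independent* four-parameter block and combine them by taking the
highest per-origin p_i for every sample — an innovation can reach a site
from whichever origin explains it best. Scaling constants (mean/sd of
point-calibrated dates; per-origin mean/sd of distances) are computed once
on the analysis dataset and reused for every model and prediction surface,
so blocks are comparable across fits. Priors are Normal(0, 10) on every β
after scaling; θ_i uniform over curve support.

## MCMC

All posteriors are sampled with an adaptive random-walk
Metropolis-within-Gibbs scheme written for this package:

* Regression/block coefficients update coordinate-wise with Gaussian
  proposals; each coordinate's step size is tuned toward 44% acceptance in
  batches of 50 during burn-in only (Robbins-Monro decay), then frozen, so
  the post-adaptation chain targets the stated posterior exactly.
* Latent calendar ages are conditionally independent given the parameters,
  so all θ_i update in one vectorised elementwise Metropolis sweep per
  iteration, each with its own adapted step size. Proposals outside the
  curve support are rejected states (−∞), not errors.
* The quantile model is sampled on the centred-distance parameterisation
  μ = a₀ + γ₁ (d − d̄), a pure reparameterisation that removes the strong
  γ₀–γ₁ posterior correlation; draws are reported on the original scale.
* Diffusion chains are initialised at per-origin ridge-penalised logistic
  MAP fits (plus jitter). The max-combination posterior can hold a minor
  mode in which one origin is "switched off" (its block drifts to never
  winning); data-informed starts keep desk-scale chains in the joint mode.
  This is the model's known pathology, not an implementation artefact —
  weakly-winning origins are weakly identified by construction, and their
  wide posteriors reflect that.

Default layout: 4 chains, half the iterations discarded as burn-in, even
thinning to at most 10,000 retained draws per chain. Desk-scale defaults
(10,000 iterations; the analysis scripts use 2,000–8,000) keep every fit in
seconds-to-minutes; production-scale runs (100,000 iterations for the
quantile models, 500,000 for the binomial models) use the same code with a
larger `n_iterations`. Convergence is summarised by split-chain
rank-normalised R̂ (flagged above 1.01, reported as a warning, never a
crash) and autocorrelation-based ESS with Geyer's initial
positive-sequence truncation, capped at the total draw count. A constant
chain returns ESS 1 with a warning.

## WAIC and model weights

Model comparison uses WAIC on the **Bernoulli term only**: the calibration
measurement model is shared nuisance structure across all seven models, so
the pointwise log-likelihood matrix stores log p(y_i | draw). Per
observation, lppd_i = log mean_s exp(ll_si) (log-sum-exp stabilised) and
the penalty is the pWAIC2 pointwise sample variance (ddof = 1);
WAIC = −2(Σ lppd_i − Σ p_i). Weights are the Akaike transform
exp(−Δ/2)/Σ exp(−Δ/2) of the WAIC differences from the best model. The
WAIC standard error is computed but not used for ranking.

## Residual hotspots

Residuals r_i = y_i − posterior-mean p_i are screened per time slice.
A sample belongs to the slice centred at T when its calibrated probability
mass on [T + 500, T − 500] exceeds 0.5 (strictly — "over" one half).
Spatial weights default to binary k-nearest neighbours with k = 8
(configurable; a fixed distance band is also available); the statistic is
the Getis-Ord **Gi** form that excludes the focal point, standardised with
leave-one-out mean and SD. Significance uses the conditional permutation
test: the focal value stays fixed, the remaining values are shuffled across
the other locations (999 permutations), and the two-sided p-value is
(1 + #{|Gi*| ≥ |Gi|})/(1 + 999). Slices with fewer than three members are
skipped with a warning. No multiplicity correction is applied across
points; raw permutation p-values are reported.

## Synthetic study conditions

The generator emulates the *structure* of a Saharan-scale presence/absence
chronology with known truth:

* 259 sites uniform in the lon [−17, 37]°E × lat [10, 34]°N box; three
  candidate origins at the study coordinates (Bir Kiseiba 30.02°E 22.65°N,
  Adrar Bous 9.03°E 20.32°N, Ounjougou −3.23°E 14.63°N).
* Dates per site: 1 + Poisson(2), each either a new uniform draw from the
  12,000–7,500 cal BP window or a ±40-yr near-duplicate of the previous
  date (probability ½), so the 100-yr binning stage always has work to do.
* Presence from the forward diffusion model at the true blocks; defaults
  (b₀, β_time, β_distance, β_interaction) = Bir Kiseiba (−1.0, 1.2, 2.0,
  0.3), Adrar Bous (−0.5, 1.0, 2.6, 0.5), Ounjougou (−0.8, 1.5, 2.2, 0.0)
  on scaled covariates. These were chosen once to encode genuinely
  *local, separable* origin signals — strong distance decay, distinct
  temporal profiles, one accelerating interaction — with an overall
  presence fraction near 0.7. Weaker or strongly overlapping blocks make
  the middle origin unidentifiable (its covariates correlate with its
  neighbour's over this geometry), which is a property of the max-combined
  model, not of the sampler.
* Front-regression truth: γ₀ = 10,500 cal BP, γ₁ = −0.5 yr/km (a 2 km/yr
  front), λ = 100 yr — with τ = 0.05 the occupation dates scatter up to
  ~2,000 yr after first arrival, a realistic persistence span. Draws are
  truncated at the curve support (not the analysis window) so the fitted
  likelihood matches the generative one apart from a negligible tail clip.
* Observed ¹⁴C ages pass through the forward measurement model on the
  "wiggle" test curve f(θ) = θ + 25 sin(θ/40) with constant 15-yr curve
  error — single-valued (amplitude < period) but non-trivially non-linear —
  and lab errors uniform on [40, 120] yr. The identity curve is used in
  unit tests only.

Deliberately **not** emulated: the clustering of real sites along wadis and
massifs, taphonomic loss, research-intensity bias, marine/reservoir
effects, and stratigraphic constraints between samples. Passing tests
therefore demonstrate that the estimators recover known truth under the
stated sampling structure, not that the real-data conclusions are robust
to those survey biases.

## Test and acceptance problem sizes

The test-suite and acceptance-script simulation sizes are desk-scale
choices: front-slope null studies use 20 replicates of 100 dates with
2-chain, 3,000-iteration fits; model selection uses 10 replicates of ~300
samples at 6,000 iterations; parameter recovery uses one ~500-sample
dual-origin study at 8,000 iterations plus a 20-replicate coarse
simulation-based-calibration check (95% intervals covering truth in
80–100% of replicates). The recovery study uses the two well-separated
origins (Bir Kiseiba and Ounjougou, ~3,400 km apart) because the
middle-origin block of a triple study is only weakly identified at this
sample size (see above).

## Known limitations

* Random-walk MCMC, not gradient-based: long production runs are slow in
  pure Python, and the multimodal max-combination posterior relies on
  data-informed initialisation rather than mode-jumping moves.
* WAIC conditions on the latent calendar ages (the Bernoulli partition);
  marginalising them is a defensible alternative that was not published
  for the original analysis and is not implemented.
* The Gi weights scheme (k = 8 binary k-NN) is a default, not a published
  choice; conclusions about specific clusters can shift with the scheme.
* No anisotropic or direction-dependent diffusion, no spatial random
  effects, no marine/mixed calibration curves.
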