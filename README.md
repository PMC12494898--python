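# paleodispersal

Bayesian spatio-temporal analysis of how a technology — here, early ceramic
production across the Sahara/Sahel belt — spread from one or several points
of origin, inferred from radiocarbon-dated presence/absence evidence.

The package addresses two linked questions archaeologists ask of a dated
presence/absence database:

1. **Is a single origin plausible?** For each candidate origin, a Bayesian
   quantile regression models the *early edge* of the dated distribution as
   a function of great-circle distance `d` from the origin, using the
   asymmetric Laplace likelihood at τ = 0.05:

   θᵢ ~ AsymLaplace(γ₀ + γ₁ dᵢ, λ, τ),  xᵢ ~ Normal(f(θᵢ), σᵢ)

   where θᵢ is the latent calendar age, xᵢ the observed ¹⁴C age, f the
   calibration curve and σᵢ combines the lab and curve errors in
   quadrature. A slope interval that includes 0 means distance from that
   origin does not predict arrival times.

2. **How many origins, and where?** A binomial diffusion model for the
   presence flag yᵢ:

   yᵢ ~ Bernoulli(pᵢ),
   logit(pᵢ) = β₀ − β_time θᵢ − β_distance dᵢ + β_interaction dᵢ θᵢ

   fitted per origin on scaled, centred covariates; multi-origin models give
   every origin its own parameter block and take the **maximum** per-origin
   probability for each sample. The seven origin combinations are compared
   by WAIC with Akaike-type evidence weights, and residuals (yᵢ − E[pᵢ]) are
   screened for local spatial clustering with Getis-Ord Gi permutation
   tests by time slice — clusters betray directionality the isotropic model
   cannot express.

All fits propagate chronological uncertainty by sampling the latent calendar
ages jointly with the model parameters (adaptive Metropolis-within-Gibbs).
A ground-truth synthetic-study generator makes the entire pipeline testable
without any external data.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 1 --n-sites 60
python analysis/02_prepare_data.py
python analysis/03_fit_front_regression.py --iterations 2000
```

which prints (seed 1):

```
loaded 175 dates; retained 143 after binning/thinning (105 ceramic-present, 38 absent)
bir_kiseiba: slope 0.022 yr/km [-0.143, 0.185] (includes 0 -> no front signal), max R-hat 1.008
adrar_bous: slope -0.310 yr/km [-0.438, -0.174] (excludes 0 -> front signal), max R-hat 1.004
ounjougou: slope -0.180 yr/km [-0.309, -0.040] (excludes 0 -> front signal), max R-hat 1.015
```

Reading: 175 simulated dates collapse to 143 after same-site dates within
100 ¹⁴C yr are binned and one lowest-error representative kept per bin. The
front slope is in calendar years per km on the cal BP axis, so a *negative*
slope means arrival gets younger with distance (outward spread); for this
three-origin synthetic truth no single origin explains the whole front —
the eastern candidate shows no signal while the central/western ones absorb
part of the pattern, exactly the ambiguity the multi-origin binomial
comparison (`analysis/04_fit_diffusion_models.py`) is designed to resolve.
`05_probability_surfaces.py` and `06_residual_hotspots.py` then map the
posterior presence probability through time and screen the residuals for
spatial clusters.

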