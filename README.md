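# gradientzi

Zero-inflated count modelling of container-breeding mosquito abundance
along environmental gradients.

## The problem

Two closely related *Aedes* mosquitoes — the urban-adapted Asian tiger
mosquito (*Ae. albopictus*) and its forest relative (*Ae. flavopictus*) —
co-exist along forested altitudinal gradients in their native range.
Their pre-imaginal abundance (4th-instar larvae and pupae in ovitraps)
responds not only to the *mean* of environmental conditions but to their
variability: the SD and kurtosis of temperature, humidity, rainfall and
remotely sensed vegetation indices. Quantifying those responses requires
a pipeline that handles excess zeros (many traps are never colonised, or
dry out), spatial dependence among nearby traps, and autocorrelated
biweekly time series.

This package implements that pipeline end to end, with a synthetic-data
generator that emulates the field study design (27 trapped trees on 3
transects over a 109–320 m gradient, 51 biweeks, ~40% of satellite image
dates lost to cloud), so every stage is testable without any downloads.

## The models

**Zero-inflated count regression** (the core engine, a scikit-learn-style
estimator `ZeroInflatedCountRegressor`): observed counts follow a mixture

    P(Y = 0) = π + (1 − π) f(0; λ, θ)
    P(Y = y) = (1 − π) f(y; λ, θ),    y > 0

with logit(π) = zᵀγ (structural zeros — unsuitable habitat) and
log(λ) = xᵀβ, where *f* is Poisson or negative binomial (NB2: variance
λ + λ²/θ; θ is reported as "overdispersion"). Fitting is by maximum
likelihood (BFGS with analytic gradients), inference by Wald z for the
count part and likelihood-ratio χ² for zero-part terms, with AIC-based
backward elimination for model selection. Per-observation weights (e.g.
number of water-holding ovitraps) enter as frequency multipliers or,
optionally, as an exposure offset. `exp(β_j)` is the multiplicative
abundance change per unit increase of covariate *j*.

Around the engine:

- **vegindex** — ESRI ASCII band grids, DOS1 dark-object subtraction,
  NDVI `(nir−red)/(nir+red)` and EVI
  `(nir−red)/(nir+6·red−7.5·blue+1)`, per-site pixel extraction and
  loess smoothing (span 0.2, local linear).
- **covariates** — biweekly mean/SD/Pearson-kurtosis series of daily
  weather, cumulative rainfall, per-site water-temperature moments,
  distance to urban land from a land-cover grid.
- **spatialdiag** — Moran's I on model residuals with a 66 m radius
  neighbour graph and Monte Carlo permutation inference.
- **temporal** — ACF/PACF, an AR(1) null model of abundance,
  pre-whitened cross-correlation functions, and selection of
  covariate-leading lags (≤ 3 biweeks) into a lagged design.
- **thresholds** — WTp50, the water temperature where the
  structural-zero probability is 50%, solved from the zero part
  (`WTp50 = −intercept/slope`) with a delta-method SE.
- **synthgen** — seeded generators for all of the above.

## Worked example

```sh
gradientzi run --out demo --seed 0
```

runs simulate → vegetation indices → covariates → spatial fits with
Moran diagnostics → temporal lag selection and fits → WTp50, and prints
a report. Excerpts from the run above (your output with the same seed is
identical):

```
[spatial: albopictus] family=poisson AIC=24.14 n=27
  count altitude           est= 0.1626 se=0.0540 z= 3.008 p=0.002632 change=1.177
  zero  dist_urban         est= 0.0604 se=0.0378 z= 0.954 p=0.3398
  Moran's I = 0.0462 (MC p = 0.1520)
...
[temporal: albopictus] AR(1) phi=0.365; AIC=993.75
  selected lag 1 for mean_tmean (r=0.362)
  ...
  WTp50 = 12.24 C
```

Reading it: the urban species' abundance rises ~18% per metre of
altitude in this synthetic draw (`change = exp(estimate)`), its model
residuals show no significant spatial autocorrelation (Moran's I MC
p = 0.152), biweekly mean temperature leads abundance by one biweek, and
below ~12 °C ovitrap water, a zero count is more likely structural
(unsuitable conditions) than a draw from the count process.

The same stages are available individually (`gradientzi simulate`,
`vegindex`, `covars`, `fit`, `moran`, `temporal`, `wtp50`) on files, and
as library functions.

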