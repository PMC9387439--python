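# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical and design choices behind `gradientzi`.

## Zero-inflated count regression

Counts per ovitrap are modelled as a two-component mixture: with
probability π an observation is a *structural* zero (the trap is not
colonisable — too far from source populations, too cold), and with
probability 1 − π it is a draw from a count distribution with mean λ.
The zero part is logit-linear in its covariates, the count part
log-linear. The count family is Poisson or negative binomial in the NB2
parameterisation — mean λ, size θ, variance λ + λ²/θ — with θ reported
as "overdispersion"; the ZIP model is the θ → ∞ limit.

**Likelihood and optimisation.** The log-likelihood is
`log(π + (1−π) f(0))` for zeros and `log(1−π) + log f(y)` otherwise,
evaluated with log-space mixtures (`logaddexp`, softplus) so extreme
linear predictors do not overflow. Maximisation is quasi-Newton (BFGS)
with analytic gradients for β, γ and log θ (θ is estimated on the log
scale to enforce positivity; its SE is delta-method transformed back).
Starting values come from a Poisson GLM on the positive counts (count
part) and a logistic regression on the zero indicator (zero part), with
a method-of-moments start for θ. The gradient-norm tolerance is 1e-8; a
fit that does not meet a relaxed criterion is returned with
`converged_ = False` and a warning, never silently.

**Inference.** The covariance matrix is the inverse of the numerically
differentiated observed information at the MLE (symmetrised; a singular
information falls back to the pseudoinverse with a warning). Count-part
p-values are two-sided normal (Wald); zero-part terms can additionally
be tested by likelihood-ratio χ² against the model with the term
removed, which is more reliable when the zero part is weakly identified.

**Weights.** "Abundance weighted by the number of water-holding traps"
is implemented as frequency weights multiplying per-observation
log-likelihood contributions (the default). The alternative reading — a
trap-count exposure scaling the mean, λ = w·exp(xᵀβ) — is available via
`weights_mode="offset"`. Doubling frequency weights doubles the
log-likelihood but leaves point estimates unchanged.

**Model selection.** Backward elimination refits the model with each
single count-part term removed and accepts the drop with the lowest
AIC (= 2k − 2ℓ), stopping when no drop lowers AIC. Exact AIC ties
(< 1e-8) drop the term listed later in the formula. Zero-part terms are
eligible only when requested. Candidates whose fit fails are skipped
with a warning, not fatal.

**Known limits.** When cold biweeks have both λ ≈ 0 and all-zero counts,
the zero part is separable: the temperature slope can drift to very
large magnitudes with an essentially flat likelihood. The WTp50 ratio
−intercept/slope remains stable in practice, but its Wald SE is then
unreliable (the LR test is the better significance summary). No hurdle
models, random effects or Bayesian fitting are provided.

## WTp50

With zero part logit(π) = a + b·WT, the threshold WTp50 = −a/b is the
water temperature at which a zero is equally likely structural or
sampling; π(WTp50) = 0.5 exactly, and the threshold is invariant to
rescaling (a, b) jointly. The SE uses the first-order delta method,
grad = (−1/b, a/b²), over the zero-part coefficient covariance; a Monte
Carlo check in the tests confirms it within 15% in well-conditioned
cases. The delta method was chosen because the quantity is a smooth
ratio with an estimated covariance readily available; like any
first-order expansion it degrades when b is small relative to its SE.

## Moment covariates

SD uses the n−1 denominator. Kurtosis is the Pearson coefficient
m₄/m₂² from biased central moments, so a normal sample scores ≈ 3,
leptokurtic > 3 (relatively more mass in the extremes than around the
mean), platykurtic < 3; an excess (−3) variant and the small-sample
bias-corrected form are flags. Kurtosis needs ≥ 4 non-constant values
and SD ≥ 2; degenerate inputs yield NaN rather than exceptions. Biweeks
are consecutive 14-day blocks from the configured start date; rainfall
is additionally cumulated per biweek (aggregation conserves the total),
and its SD/kurtosis use the daily values within each biweek. Water
temperature at dry biweeks is excluded from site moments, not imputed.

## Vegetation indices

Bands are DOS1-corrected by subtracting the per-band dark-object value
(the 1st-percentile reflectance by default, configurable to the
minimum) and clipping at zero; the correction is idempotent on a band
that already contains a true zero. NDVI is (nir−red)/(nir+red); EVI is
(nir−red)/(nir+6·red−7.5·blue+1) with a gain parameter defaulting to 1
(pass 2.5 for the conventional gain). Zero denominators yield NaN with
a warning. Site extraction uses half-open raster cells
[x, x+cell) × [y, y+cell) — a point on an upper edge belongs to the
next cell — which is deterministic and matches standard raster
conventions. Image discarding is a quality flag supplied with the data;
no cloud detection is attempted.

Loess smoothing is local *linear* regression with tricube weights over
the span·n nearest points (statsmodels lowess, no robustness
iterations), fitted on the available points against the real time index
so gaps from discarded dates do not shrink the local windows, and
evaluated at every retained time point. Degree-1 loess reproduces
exactly linear series at any span. Note that at span 1.0 the fit is
still a *tricube-weighted* line at each evaluation point, not the
ordinary least-squares line; the tests check it against a closed-form
weighted-regression oracle.

## Spatial diagnostics

Neighbours are all sites within a fixed radius (66 m in the emulated
design — the largest minimum inter-site distance, so no site is
isolated); weights are 1/(number of neighbours), so rows with
neighbours sum to one. Isolated sites keep an empty row (contributing
to the variance term but not to S₀) with a warning. Moran's I uses the
standard cross-product form with null expectation −1/(n−1); the Monte
Carlo test permutes values across sites and reports
p = (1 + #extreme)/(n_reps + 1), one-sided "greater" by default since
the concern is positive residual autocorrelation (two-sided compares
|I − E[I]|). The +1 correction keeps p ≥ 1/(n_reps+1).

## Temporal analysis

The ACF uses the standard biased estimator on complete series and
pairwise-complete averages when values are missing; the PACF comes from
the Durbin–Levinson recursion on that ACF. The null abundance model is
AR(p) by conditional least squares (order 1 in the emulated design,
chosen from the PACF cut-off; configurable); an unstable estimate warns
but is returned. Pre-whitening filters the covariate with the
*response's* AR coefficients (x′_t = x_t − Σφᵢ x_{t−i}; φ = 0 is the
identity) and cross-correlates it with the AR residuals, which removes
lag correlations that arise merely from shared autocorrelation.

The CCF is normalised by the series length and the overall (not
per-lag) standard deviations — the standard sample CCF, which differs
from the Pearson correlation of shifted arrays by O(1/n). White-noise
95% bounds are ±1.96/√N. Lag convention, stated everywhere: **lag k
means the covariate value k biweeks before the response**; only
covariate-leading lags 0–3 are eligible for selection, the maximum
|r| exceeding the bound wins, and ties go to the smaller lag.
Covariates with no significant leading lag are dropped. The lagged
design drops the first max-lag rows (51 biweeks → 48 usable), carries a
lag-1 response term, contemporaneous water temperature for the zero
part, and the wet-trap weights; missing responses keep the time axis
regular with weight zero.

## Synthetic-data generator

The generator reproduces the *structure* the analysis assumes, with the
study design as defaults: 27 sites on 3 radial transects spanning
109–320 m (altitudes linear in distance from the hilltop, so low sites
sit near the urban ring at the grid border, and distance to urban land
is computed from the land-cover grid rather than sampled — the spatial
stages stay internally consistent); 51 biweeks of daily weather from a
seasonal sinusoid (period 26 biweeks, mean 15.5 °C, amplitude 10.5 °C,
so winter biweeks fall below 10 °C) with Gaussian noise and
zero-inflated gamma rainfall; biweekly blue/red/NIR grids whose
greenness field follows the season and the hill, with an additive haze
offset per band per date (removed by DOS1) and 40% of dates discarded;
trap drying odds increasing with altitude (logit slope 0.012/m); and
water temperature tracking air temperature with a 0.45 buffering
factor, an altitudinal lapse, and episodic heating spikes whose odds
grow with canopy-openness variability — the spikes are what make the
series leptokurtic, and their implied *population* kurtosis (≈ 2.3–2.9
across sites) enters the generative count model while the pipeline
later re-estimates noisy sample kurtosis from the series, a realistic
errors-in-variables gap.

Counts are drawn from the zero-inflated models with the published
fitted coefficients as the true values: the forest species is ZINB
(θ = 6.68) over aspect, roughness, canopy SD, urban distance,
water-temperature SD and EVI moments; the urban species is ZIP over
altitude, canopy SD, water-temperature kurtosis and the other species'
mean abundance, with structural zeros (drawn once per site) increasing
with distance to urban land. Both species receive a seasonal share of
their per-site mean across biweeks, a latent AR(1) disturbance on the
log mean (φ = 0.4, σ = 0.3 — the fitted AR(1) structure used as the
generative one), and zero counts whenever a trap is dry. Optional
scripted losses reproduce the snowstorm (biweek 46, 3 traps) and
vandalism (biweek 51, 11 traps) missingness; off by default.

Randomness follows one master seed; every stage draws from an
independent child stream (`SeedSequence(seed, spawn_key=(stage,))`), so
each stage is reproducible in isolation.

**What the generator does not emulate** — and hence what passing tests
do not show about field data: real cloud masks and sensor artefacts
(discarding is random, not weather-driven), inter-trap dispersal and
density dependence, observation error in counts, the coupling between
rainfall and trap water, and the full covariance structure among
landscape covariates. Totals and per-species site occupancy come out at
the right order of magnitude (hundreds of forest-species individuals
network-wide; the urban species confined to a few low-altitude sites)
but are not calibrated to any particular observed totals.

## Test and demo problem sizes

Calibration checks run at the scale the package is meant for: ZINB
recovery uses 100 replicates of n = 1000 with the published
coefficient values on centred covariates (centring keeps the intercept
well identified; the slopes are unaffected); Moran's I type-I error
uses 1000 null datasets on a 27-site layout with 199 permutations each;
lag recovery uses 50 replicates of 51-biweek series. The demo pipeline
(`gradientzi run`) completes in a few seconds on one CPU with 999
Moran permutations.
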