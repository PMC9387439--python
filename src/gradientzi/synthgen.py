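"""Synthetic study generator.

Emulates a two-year ovitrap survey of two container-breeding *Aedes*
species along a forested altitudinal gradient ringed by urban land:
27 focal trees on 3 transects spanning 109-320 m, sampled over 51
biweeks, with daily weather from a nearby station, biweekly reflectance
band grids (blue/red/NIR, 40% of dates discarded for cloud cover), and
per-trap counts of 4th-instar larvae + pupae drawn from zero-inflated
count models.

Default "true" coefficients are the fitted values of the motivating
study's abundance models: the urban-adapted species (*albopictus*-like)
has structural-zero probability increasing with distance to urban land
and counts increasing with altitude and water-temperature kurtosis; the
forest species (*flavopictus*-like) is negative-binomial with counts
shaped by aspect, roughness, canopy variability, distance to urban land,
water-temperature SD and EVI moments.  Covariate scales (canopy ranges,
water-temperature buffering, urban-ring geometry) are chosen to keep the
linear predictors in the realistic regime those coefficients imply.

Random-number contract: one master ``seed``; each stage draws from an
independent child stream ``SeedSequence(seed, spawn_key=(stage,))``, so
any stage is reproducible on its own and insensitive to the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from gradientzi import covariates as _cov
from gradientzi import vegindex as _veg
from gradientzi.vegindex import AsciiGrid

__all__ = [
    "SyntheticConfig",
    "StudyData",
    "generate_sites",
    "generate_landcover",
    "generate_weather",
    "generate_bands",
    "draw_zi_counts",
    "generate_counts",
    "simulate_study",
]

# stage ids for independent child RNG streams
_STAGES = {"sites": 0, "weather": 1, "water": 2, "counts_a": 3,
           "counts_f": 4, "bands": 5, "missing": 6, "losses": 7}


def _default_count_coefs():
    # forest-species spatial count part (log link)
    return {"Intercept": 12.117, "aspect": 0.002, "roughness": 0.071,
            "sd_canopy": -0.072, "dist_urban": 0.006,
            "sd_water_temp": -2.435, "mean_evi": 0.153, "kurt_evi": -0.445}


def _default_zero_coefs():
    # urban-species zero part (logit link): structural zeros far from town
    return {"Intercept": -1.583, "dist_urban": 0.033}


@dataclass
class SyntheticConfig:
    """Study-design knobs for the synthetic gradient survey.

    The defaults are the study conditions the pipeline is meant to
    emulate: 27 sites in 3 transects over 109-320 m, 51 biweeks starting
    June 2014, 40% of image dates discarded, trap drying odds increasing
    with altitude, and table-derived true coefficients.
    """

    n_sites: int = 27
    altitude_range: tuple = (109.0, 320.0)
    n_biweeks: int = 51
    n_transects: int = 3
    start_date: str = "2014-06-01"
    true_count_coefs: dict = field(default_factory=_default_count_coefs)
    true_zero_coefs: dict = field(default_factory=_default_zero_coefs)
    overdispersion: float = 6.68          # NB size theta
    image_missing_frac: float = 0.40
    dry_prob_slope: float = 0.012         # per-m logit slope of trap drying
    dry_prob_intercept: float = -2.5
    scripted_losses: bool = False         # snowstorm/vandalism trap losses
    seed: int = 0

    # weather model (daily): seasonal sinusoid, period 26 biweeks
    temp_mean: float = 15.5
    temp_amp: float = 10.5
    temp_noise: float = 1.5
    diurnal_offset: float = 4.0
    rh_mean: float = 72.0
    rh_amp: float = 8.0
    rain_zero_prob: float = 0.55
    rain_shape: float = 0.8
    rain_scale: float = 12.0

    # geometry: hill centre at origin, urban ring at the grid border
    cellsize: float = 30.0
    half_extent: float = 360.0
    urban_ring_cells: int = 2
    r_inner: float = 40.0
    r_outer: float = 300.0

    # latent per-site AR(1) noise on the log count mean
    ar_phi: float = 0.4
    ar_sigma: float = 0.3

    # water temperature: buffered tracking of air temperature
    wt_buffer: float = 0.45
    wt_lapse: float = 0.0065              # deg C per m altitude

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        lo, hi = self.altitude_range
        if not lo < hi:
            raise ValueError("altitude_range must satisfy min < max")
        if not 0.0 <= self.image_missing_frac <= 1.0:
            raise ValueError("image_missing_frac must be in [0, 1]")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion (theta) must be positive")
        if self.n_biweeks < 1:
            raise ValueError("n_biweeks must be >= 1")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent child stream for a named pipeline stage."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],)))


def generate_landcover(config: SyntheticConfig) -> AsciiGrid:
    """Land-cover grid: vegetation (0) inside an urban (1) border ring."""
    n = int(round(2 * config.half_extent / config.cellsize))
    vals = np.zeros((n, n))
    k = config.urban_ring_cells
    vals[:k, :] = 1
    vals[-k:, :] = 1
    vals[:, :k] = 1
    vals[:, -k:] = 1
    return AsciiGrid(vals, xll=-config.half_extent, yll=-config.half_extent,
                     cellsize=config.cellsize, band="landcover")


def generate_sites(config: SyntheticConfig) -> pd.DataFrame:
    """Site table: focal trees on radial transects down the hillside.

    Altitudes span the configured range exactly (linear in distance from
    the hilltop, so edge-proximal sites are low and urban-close).
    ``dist_urban`` is computed from the land-cover grid, keeping the
    spatial stages internally consistent.
    """
    rng = config.rng("sites")
    lo, hi = config.altitude_range
    alts = np.linspace(hi, lo, config.n_sites)
    transect = np.arange(config.n_sites) % config.n_transects
    base_angle = 2 * np.pi * transect / config.n_transects
    angle = base_angle + rng.normal(0.0, 0.12, config.n_sites)
    radius = config.r_inner + (hi - alts) / (hi - lo) * (config.r_outer -
                                                         config.r_inner)
    x = radius * np.cos(angle)
    y = radius * np.sin(angle)
    sites = pd.DataFrame({
        "id": [f"S{i + 1:02d}" for i in range(config.n_sites)],
        "x": x, "y": y,
        "altitude": alts,
        "transect": [f"T{t + 1}" for t in transect],
        "aspect": (np.degrees(base_angle) + rng.normal(0, 30, config.n_sites))
                  % 360.0,
        "roughness": np.abs(rng.normal(3.0, 1.5, config.n_sites)),
        "tpi": rng.normal(0.0, 1.0, config.n_sites),
        "mean_canopy": rng.uniform(60.0, 95.0, config.n_sites),
        "sd_canopy": rng.uniform(2.0, 15.0, config.n_sites),
        "ground_index_1": rng.normal(0.0, 1.0, config.n_sites),
        "ground_index_2": rng.normal(0.0, 1.0, config.n_sites),
    })
    landcover = generate_landcover(config)
    sites["dist_urban"] = _cov.distance_to_urban(landcover, sites).to_numpy()
    return sites


def generate_weather(config: SyntheticConfig) -> pd.DataFrame:
    """Daily weather: seasonal sinusoid (period 26 biweeks) plus noise.

    Guarantees ``tmin <= tmean <= tmax``; rainfall is zero-inflated
    gamma.  With zero amplitude and zero noise the temperature series are
    constant.
    """
    rng = config.rng("weather")
    n_days = 14 * config.n_biweeks
    dates = pd.date_range(config.start_date, periods=n_days, freq="D")
    t = np.arange(n_days)
    peak = 65.0  # days from the June start to the warmest day (early Aug)
    season = config.temp_amp * np.cos(2 * np.pi * (t - peak) / 364.0)
    noise = (config.temp_noise * rng.normal(0, 1, n_days)
             if config.temp_noise > 0 else 0.0)
    tmean = config.temp_mean + season + noise
    spread = config.diurnal_offset + (
        config.temp_noise * np.abs(rng.normal(0, 0.5, n_days))
        if config.temp_noise > 0 else 0.0)
    rh = np.clip(config.rh_mean
                 + config.rh_amp * np.sin(2 * np.pi * (t - peak) / 364.0)
                 + (4.0 * rng.normal(0, 1, n_days) if config.temp_noise > 0
                    else 0.0), 20.0, 100.0)
    wet = rng.random(n_days) >= config.rain_zero_prob
    rain = np.where(wet, rng.gamma(config.rain_shape, config.rain_scale,
                                   n_days), 0.0)
    return pd.DataFrame({"date": dates, "tmax": tmean + spread,
                         "tmean": tmean, "tmin": tmean - spread,
                         "rh": rh, "rainfall": rain})


def generate_bands(config: SyntheticConfig, sites: pd.DataFrame | None = None):
    """Biweekly blue/red/NIR reflectance grids plus the retained-date list.

    Vegetation greenness is highest at the hill centre, follows the
    season (period 26 biweeks) and is depressed in the urban ring; each
    band per date carries an additive haze offset for DOS1 to remove.
    Roughly ``image_missing_frac`` of the dates are flagged discarded.

    Returns ``(bands, retained)`` where ``bands[biweek][band]`` is an
    :class:`AsciiGrid` and `retained` lists quality-passing biweeks.
    """
    rng = config.rng("bands")
    landcover = generate_landcover(config)
    n = landcover.values.shape[0]
    cx = np.arange(n) + 0.5
    xg, yg = np.meshgrid(landcover.xll + cx * config.cellsize,
                         landcover.yll + cx * config.cellsize)
    r = np.hypot(xg, yg)
    base_green = np.where(landcover.values[::-1] == 1, 0.15,
                          0.75 - 0.25 * r / r.max())[::-1]
    n_missing = int(round(config.image_missing_frac * config.n_biweeks))
    discarded = set(config.rng("missing").choice(config.n_biweeks,
                                                 size=n_missing,
                                                 replace=False).tolist())
    retained = [b for b in range(config.n_biweeks) if b not in discarded]
    bands = {}
    for bw in range(config.n_biweeks):
        f = 0.75 + 0.25 * np.cos(2 * np.pi * (bw - 4.5) / 26.0)
        g = np.clip(base_green * f + rng.normal(0, 0.02, (n, n)), 0.02, 0.98)
        haze = rng.uniform(0.0, 0.05, size=3)
        grids = {
            "blue": 0.03 + 0.10 * (1 - g) + haze[0],
            "red": 0.04 + 0.25 * (1 - g) + haze[1],
            "nir": 0.10 + 0.45 * g + haze[2],
        }
        bands[bw] = {
            nm: AsciiGrid(v, xll=landcover.xll, yll=landcover.yll,
                          cellsize=config.cellsize, band=nm, biweek=bw)
            for nm, v in grids.items()
        }
    return bands, retained


def _eta(design: pd.DataFrame, coefs: dict, part: str) -> np.ndarray:
    missing = [k for k in coefs if k != "Intercept"
               and k not in design.columns]
    if missing:
        raise ValueError(f"{part}-part coefficient name(s) not in design "
                         f"matrix: {missing}")
    eta = np.full(len(design), float(coefs.get("Intercept", 0.0)))
    for nm, c in coefs.items():
        if nm != "Intercept":
            eta = eta + c * design[nm].to_numpy(dtype=float)
    return eta


def draw_zi_counts(design: pd.DataFrame, count_coefs: dict, zero_coefs: dict,
                   theta: float | None = None, exposure=None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw zero-inflated counts for the rows of a design matrix.

    Structural-zero probability ``pi = logistic(z @ gamma)``; count mean
    ``lam = exp(x @ beta) * exposure``.  ``theta=None`` gives Poisson
    counts (the NB limit theta -> infinity), otherwise NB2 with size
    `theta`.  Coefficients are named; a name absent from the design
    raises listing the missing names.
    """
    rng = np.random.default_rng() if rng is None else rng
    eta_c = _eta(design, count_coefs, "count")
    eta_z = _eta(design, zero_coefs, "zero")
    lam = np.exp(eta_c)
    if exposure is not None:
        lam = lam * np.asarray(exposure, dtype=float)
    pi = expit(eta_z)
    structural = rng.random(len(lam)) < pi
    if theta is None:
        counts = rng.poisson(lam)
    else:
        counts = rng.negative_binomial(theta, theta / (theta + lam))
    counts[structural] = 0
    return counts


def generate_counts(sites: pd.DataFrame, design: pd.DataFrame,
                    config: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Counts from the configured true coefficients (ZINB; ZIP as theta→∞)."""
    theta = config.overdispersion if np.isfinite(config.overdispersion) \
        else None
    return draw_zi_counts(design, config.true_count_coefs,
                          config.true_zero_coefs, theta=theta,
                          rng=rng if rng is not None else config.rng("counts_f"))


@dataclass
class StudyData:
    """Everything the pipeline consumes, generated from one config."""

    config: SyntheticConfig
    sites: pd.DataFrame
    weather: pd.DataFrame
    landcover: AsciiGrid
    bands: dict
    retained_biweeks: list
    ovitraps: pd.DataFrame           # long panel: site x biweek
    evi_series: pd.DataFrame         # (site, biweek, value) for retained dates
    ndvi_series: pd.DataFrame

    def write(self, outdir) -> None:
        """Write all inputs as plain-text files under `outdir`."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(out / "sites.csv", index=False)
        self.weather.to_csv(out / "weather.csv", index=False)
        self.ovitraps.to_csv(out / "ovitraps.csv", index=False)
        _veg.write_ascii_grid(self.landcover, out / "landcover.asc")
        bdir = out / "bands"
        bdir.mkdir(exist_ok=True)
        for bw in self.retained_biweeks:
            for nm, grid in self.bands[bw].items():
                _veg.write_ascii_grid(grid, bdir / f"bw{bw:02d}_{nm}.asc")


def _seasonal_share(tmean_bw: np.ndarray, strength: float) -> np.ndarray:
    z = (tmean_bw - tmean_bw.mean()) / max(tmean_bw.std(), 1e-9)
    s = np.exp(strength * z)
    return s / s.sum()


def simulate_study(config: SyntheticConfig | None = None) -> StudyData:
    """Generate a complete synthetic study from one seeded config.

    Stages: sites and land cover; daily weather; band grids with
    discarded dates; EVI/NDVI site series (DOS1-corrected); trap water
    presence/temperature (drying odds increase with altitude; water
    temperature tracks air temperature with buffering and an altitudinal
    lapse); then two species' counts:

    - ``flavopictus``: ZINB, count part from the forest-species spatial
      coefficients over site covariates (including generated EVI moments
      and water-temperature SD), a weak zero part;
    - ``albopictus``: ZIP, count part from the urban-species spatial
      coefficients (altitude, canopy SD, water-temperature kurtosis and
      the other species' mean abundance), zero part increasing with
      distance to urban land (structural zeros drawn once per site).

    Both get a seasonal share of the per-site mean across biweeks and a
    latent AR(1) disturbance on the log mean, and drop to zero when a
    trap is dry.
    """
    config = SyntheticConfig() if config is None else config
    sites = generate_sites(config)
    weather = generate_weather(config)
    landcover = generate_landcover(config)
    bands, retained = generate_bands(config, sites)

    # vegetation index site series on retained dates (DOS1 + EVI/NDVI)
    evi_grids, ndvi_grids = {}, {}
    for bw in retained:
        corr = {nm: _veg.dos1_correct(g) for nm, g in bands[bw].items()}
        evi_grids[bw] = AsciiGrid(
            _veg.evi(corr["nir"].values, corr["red"].values,
                     corr["blue"].values),
            xll=landcover.xll, yll=landcover.yll, cellsize=config.cellsize,
            band="evi", biweek=bw)
        ndvi_grids[bw] = AsciiGrid(
            _veg.ndvi(corr["nir"].values, corr["red"].values),
            xll=landcover.xll, yll=landcover.yll, cellsize=config.cellsize,
            band="ndvi", biweek=bw)
    evi_series = _veg.extract_site_values(evi_grids, sites)
    ndvi_series = _veg.extract_site_values(ndvi_grids, sites)
    evi_site = _veg.index_moments(evi_series, axis="over_time")

    # biweekly air temperature drives water temperature and seasonality
    bw_weather = _cov.biweekly_weather(weather, config.start_date,
                                       config.n_biweeks)
    tmean_bw = bw_weather["mean_tmean"].to_numpy()

    # trap water: drying odds increase with altitude
    rng_w = config.rng("water")
    lo = config.altitude_range[0]
    p_dry = expit(config.dry_prob_intercept
                  + config.dry_prob_slope * (sites["altitude"].to_numpy() - lo))
    n_s, n_b = config.n_sites, config.n_biweeks
    water_present = rng_w.random((n_s, n_b)) >= p_dry[:, None]
    site_offset = rng_w.normal(0.0, 0.5, n_s)
    # episodic heating spikes (sun flecks through canopy gaps) give the
    # water-temperature series its leptokurtic tail; spike odds scale
    # with canopy-openness variability
    p_spike = 0.02 + 0.004 * sites["sd_canopy"].to_numpy()
    spikes = (rng_w.random((n_s, n_b)) < p_spike[:, None]) \
        * rng_w.exponential(4.0, (n_s, n_b))
    wt = (config.temp_mean
          + config.wt_buffer * (tmean_bw[None, :] - config.temp_mean)
          - config.wt_lapse * (sites["altitude"].to_numpy()[:, None] - lo)
          + site_offset[:, None] + rng_w.normal(0.0, 0.6, (n_s, n_b))
          + spikes)
    wt = np.where(water_present, wt, np.nan)

    # per-site water-temperature moments feed the count models; the
    # *true* (population) kurtosis implied by the spike process enters the
    # generative design — the sample kurtosis the pipeline later estimates
    # scatters around it (errors in variables, as in the field)
    wt_sd = pd.DataFrame(wt).std(axis=1, ddof=1).to_numpy()
    kurt_true = 2.1 + 12.0 * p_spike

    site_cov = sites.set_index("id").copy()
    site_cov["sd_water_temp"] = wt_sd
    site_cov["kurt_water_temp"] = kurt_true
    site_cov["mean_evi"] = evi_site["mean"].reindex(site_cov.index).to_numpy()
    site_cov["kurt_evi"] = evi_site["kurtosis"].reindex(site_cov.index) \
                                                .to_numpy()

    def _latent_ar(rng, n_sites, n_bw):
        a = np.zeros((n_sites, n_bw))
        eps = rng.normal(0.0, config.ar_sigma, (n_sites, n_bw))
        a[:, 0] = eps[:, 0]
        for t in range(1, n_bw):
            a[:, t] = config.ar_phi * a[:, t - 1] + eps[:, t]
        return a

    def _species_counts(coefs, zero_coefs, theta, strength, stage):
        rng = config.rng(stage)
        eta_site = _eta(site_cov.reset_index(), coefs, "count")
        share = _seasonal_share(tmean_bw, strength)
        ar = _latent_ar(rng, n_s, n_b)
        lam = np.exp(np.clip(eta_site[:, None] + np.log(share)[None, :] + ar,
                             None, 8.0))
        pi_site = expit(_eta(site_cov.reset_index(), zero_coefs, "zero"))
        structural = rng.random(n_s) < pi_site
        if theta is None:
            counts = rng.poisson(lam)
        else:
            counts = rng.negative_binomial(theta, theta / (theta + lam))
        counts[structural, :] = 0
        counts[~water_present] = 0
        return counts

    counts_f = _species_counts(
        config.true_count_coefs, {"Intercept": -3.0}, config.overdispersion,
        strength=1.2, stage="counts_f")
    site_cov["flav_abundance"] = counts_f.mean(axis=1)
    coefs_a = {"Intercept": -15.547, "flav_abundance": -0.077,
               "sd_canopy": 0.036, "kurt_water_temp": 5.627,
               "altitude": 0.027}
    counts_a = _species_counts(coefs_a, config.true_zero_coefs, None,
                               strength=2.0, stage="counts_a")

    lost = np.zeros((n_s, n_b), dtype=bool)
    if config.scripted_losses:
        rng_l = config.rng("losses")
        for bw, k in ((45, 3), (50, 11)):
            if bw < n_b:
                lost[rng_l.choice(n_s, size=min(k, n_s), replace=False), bw] \
                    = True

    n_wet = water_present.sum(axis=0)
    rows = []
    for i, sid in enumerate(site_cov.index):
        for t in range(n_b):
            rows.append({
                "site": sid, "biweek": t,
                "water_present": bool(water_present[i, t]),
                "water_temp": wt[i, t],
                "count_albopictus": (np.nan if lost[i, t]
                                     else int(counts_a[i, t])),
                "count_flavopictus": (np.nan if lost[i, t]
                                      else int(counts_f[i, t])),
                "trap_lost": bool(lost[i, t]),
                "n_wet_traps_biweek": int(n_wet[t]),
            })
    ovitraps = pd.DataFrame(rows)
    return StudyData(config=config, sites=sites, weather=weather,
                     landcover=landcover, bands=bands,
                     retained_biweeks=retained, ovitraps=ovitraps,
                     evi_series=evi_series.rename(columns={"value": "evi"}),
                     ndvi_series=ndvi_series.rename(columns={"value": "ndvi"}))
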