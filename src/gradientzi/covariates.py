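"""Moment covariates: biweekly weather aggregates, per-site water
temperature moments, and distance to urban land.

Environmental covariates enter the abundance models not only through their
mean but also through their dispersion (SD) and the shape of their tails
(kurtosis) — organisms track the whole distribution of environmental
variation, not just its centre.  Kurtosis here is the Pearson
(non-excess) coefficient ``m4 / m2**2``, so a normal distribution scores 3,
leptokurtic ("more mass in the extremes than around the mean") scores
above 3 and platykurtic below.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "moments",
    "assign_biweeks",
    "biweekly_weather",
    "site_water_temp_moments",
    "distance_to_urban",
]

#: daily weather variables aggregated by mean/SD/kurtosis
WEATHER_VARS = ("tmax", "tmean", "tmin", "rh")


def moments(values, *, excess: bool = False, corrected: bool = False):
    """Mean, sample SD and kurtosis of a sequence.

    Parameters
    ----------
    values : array-like
        Observations; NaNs are dropped.
    excess : bool
        Report excess kurtosis (normal -> 0) instead of the Pearson
        coefficient (normal -> 3).
    corrected : bool
        Use the small-sample (G2-style) bias-corrected kurtosis instead of
        the plain method-of-moments ``m4/m2**2``.

    Returns
    -------
    (mean, sd, kurtosis) : tuple of floats
        SD uses the n-1 denominator and needs n >= 2; kurtosis needs
        n >= 4 and a non-constant sample.  Undefined quantities come back
        as NaN rather than raising.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n == 0:
        return (np.nan, np.nan, np.nan)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n >= 2 else np.nan
    if n < 4 or np.ptp(x) == 0.0:
        kurt = np.nan
    else:
        kurt = float(stats.kurtosis(x, fisher=excess, bias=not corrected))
    return (mean, sd, kurt)


def assign_biweeks(dates, start, n_biweeks: int) -> np.ndarray:
    """Map daily dates onto consecutive 14-day blocks starting at `start`.

    Raises ``ValueError`` for any date outside the configured calendar.
    """
    dates = pd.to_datetime(pd.Series(dates))
    start = pd.Timestamp(start)
    idx = ((dates - start).dt.days // 14).to_numpy()
    bad = (idx < 0) | (idx >= n_biweeks) | ((dates - start).dt.days.to_numpy() < 0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} day(s) fall outside the biweek calendar "
            f"[{start.date()}, {start.date()} + {n_biweeks}*14d)"
        )
    return idx.astype(int)


def biweekly_weather(daily: pd.DataFrame, start, n_biweeks: int,
                     *, corrected: bool = False) -> pd.DataFrame:
    """Aggregate a daily weather table into biweekly moment series.

    `daily` must have a ``date`` column plus ``tmax, tmean, tmin, rh,
    rainfall``.  Temperatures and relative humidity are summarised by
    mean/SD/kurtosis within each 14-day block; rainfall by the cumulative
    sum plus SD and kurtosis of the daily values.

    Returns a wide frame indexed by ``biweek`` with columns like
    ``mean_tmean``, ``sd_tmean``, ``kurt_tmean``, ``cum_rainfall`` ...
    """
    daily = daily.copy()
    daily["biweek"] = assign_biweeks(daily["date"], start, n_biweeks)
    rows = {}
    for bw, grp in daily.groupby("biweek"):
        rec = {}
        for var in WEATHER_VARS:
            m, s, k = moments(grp[var], corrected=corrected)
            rec[f"mean_{var}"] = m
            rec[f"sd_{var}"] = s
            rec[f"kurt_{var}"] = k
        rain = grp["rainfall"].to_numpy(dtype=float)
        _, s, k = moments(rain, corrected=corrected)
        rec["cum_rainfall"] = float(np.nansum(rain))
        rec["sd_rainfall"] = s
        rec["kurt_rainfall"] = k
        rows[bw] = rec
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "biweek"
    return out


def site_water_temp_moments(ovitraps: pd.DataFrame, *, min_obs: int = 4,
                            corrected: bool = False) -> pd.DataFrame:
    """Per-site mean/SD/kurtosis of ovitrap water temperature over time.

    Dry biweeks carry no water temperature and are excluded, not imputed.
    Sites with fewer than `min_obs` wet observations get NaN moments.
    """
    rows = {}
    for site, grp in ovitraps.groupby("site"):
        wt = grp.loc[grp["water_present"].astype(bool), "water_temp"]
        wt = wt.dropna()
        if len(wt) < min_obs:
            rows[site] = {"mean_water_temp": np.nan, "sd_water_temp": np.nan,
                          "kurt_water_temp": np.nan, "n_wet": len(wt)}
            continue
        m, s, k = moments(wt, corrected=corrected)
        rows[site] = {"mean_water_temp": m, "sd_water_temp": s,
                      "kurt_water_temp": k, "n_wet": len(wt)}
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "site"
    return out


def distance_to_urban(landcover, sites: pd.DataFrame) -> pd.Series:
    """Euclidean distance (m) from each site to the nearest urban cell centre.

    Parameters
    ----------
    landcover : AsciiGrid
        Grid whose cells equal 1 for urban land and 0 for vegetation.
    sites : DataFrame
        Must have ``x`` and ``y`` columns (same CRS/units as the grid).

    A site whose own cell is urban gets distance 0.  Raises ``ValueError``
    if the grid contains no urban cell.
    """
    vals = np.asarray(landcover.values)
    urb_r, urb_c = np.nonzero(vals == 1)
    if urb_r.size == 0:
        raise ValueError("land-cover grid contains no urban cell")
    ux, uy = landcover.cell_centers(urb_r, urb_c)
    out = {}
    for site, row in sites.iterrows():
        sid = row["id"] if "id" in row else site
        r, c = landcover.locate(row["x"], row["y"])
        if vals[r, c] == 1:
            out[sid] = 0.0
        else:
            out[sid] = float(np.min(np.hypot(ux - row["x"], uy - row["y"])))
    return pd.Series(out, name="dist_urban")
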