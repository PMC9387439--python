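"""Vegetation indices from reflectance band grids.

Implements the remote-sensing leg of the pipeline: ESRI ASCII grid IO,
DOS1 dark-object subtraction (a first-order atmospheric/shadow haze
correction that subtracts the darkest signal per band), NDVI and EVI,
per-site pixel extraction, and loess smoothing of the resulting biweekly
series.

The EVI used here is ``(nir - red) / (nir + 6*red - 7.5*blue + 1)`` with a
gain of 1 by default (``gain`` is configurable; the conventional
formulation multiplies by 2.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from gradientzi import covariates as _cov

__all__ = [
    "AsciiGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "dos1_correct",
    "ndvi",
    "evi",
    "extract_site_values",
    "loess_smooth",
    "smooth_index_series",
    "index_moments",
]


@dataclass
class AsciiGrid:
    """A single-band raster with ESRI ASCII grid geometry.

    ``values`` is a 2-D array with row 0 at the *top* of the map (the
    ASCII-grid convention); ``xll``/``yll`` give the lower-left corner and
    ``cellsize`` the square cell edge in the same units as site
    coordinates (metres here).
    """

    values: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 30.0
    nodata: float = -9999.0
    band: str = ""
    biweek: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a nonempty 2-D array")

    @property
    def shape(self):
        return self.values.shape

    def locate(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to (row, col) using half-open cells.

        Cells are ``[x0, x0 + cellsize) x [y0, y0 + cellsize)``: a point
        sitting exactly on an upper edge belongs to the next cell.  Raises
        ``ValueError`` when the point falls outside the grid extent.
        """
        nrows, ncols = self.values.shape
        col = int(np.floor((x - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((y - self.yll) / self.cellsize))
        if not (0 <= col < ncols and 0 <= row_from_bottom < nrows):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return nrows - 1 - row_from_bottom, col

    def cell_centers(self, rows, cols):
        """x/y coordinates of cell centres for (row, col) index arrays."""
        nrows = self.values.shape[0]
        x = self.xll + (np.asarray(cols) + 0.5) * self.cellsize
        y = self.yll + (nrows - 1 - np.asarray(rows) + 0.5) * self.cellsize
        return x, y


def read_ascii_grid(path, band: str = "", biweek: int | None = None) -> AsciiGrid:
    """Read an ESRI ASCII grid (.asc) file."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    return AsciiGrid(values, xll=header.get("xllcorner", 0.0),
                     yll=header.get("yllcorner", 0.0),
                     cellsize=header.get("cellsize", 1.0),
                     nodata=nodata, band=band, biweek=biweek)


def write_ascii_grid(grid: AsciiGrid, path) -> None:
    """Write an :class:`AsciiGrid` as an ESRI ASCII .asc file."""
    nrows, ncols = grid.values.shape
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xll}\n")
        fh.write(f"yllcorner {grid.yll}\n")
        fh.write(f"cellsize {grid.cellsize}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        np.savetxt(fh, vals, fmt="%.6g")


def dos1_correct(grid: AsciiGrid, dark_quantile: float = 0.01) -> AsciiGrid:
    """Dark-object subtraction: remove the per-band dark signal.

    The dark-object value is the `dark_quantile` quantile of the band's
    finite values (default the 1st percentile; 0 uses the minimum).  The
    corrected band is clipped below at zero, so a grid already containing
    a true zero is unchanged at ``dark_quantile=0``.
    """
    vals = grid.values
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("cannot DOS1-correct an empty/all-missing grid")
    dark = np.quantile(finite, dark_quantile)
    out = np.clip(vals - dark, 0.0, None)
    return AsciiGrid(out, xll=grid.xll, yll=grid.yll, cellsize=grid.cellsize,
                     nodata=grid.nodata, band=grid.band, biweek=grid.biweek)


def ndvi(nir, red):
    """Normalized difference vegetation index ``(nir - red)/(nir + red)``.

    Bounded in [-1, 1] for nonnegative reflectances and antisymmetric in
    its arguments.  Where ``nir + red == 0`` the index is undefined and
    returned as NaN with a warning.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = nir + red
    bad = denom == 0
    if np.any(bad):
        warnings.warn("NDVI undefined where nir + red == 0; returning NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, (nir - red) / np.where(bad, 1.0, denom))
    return out if out.ndim else float(out)


def evi(nir, red, blue, gain: float = 1.0):
    """Enhanced vegetation index ``gain*(nir - red)/(nir + 6 red - 7.5 blue + 1)``.

    ``gain`` defaults to 1; pass 2.5 for the conventional formulation.
    A zero denominator yields NaN with a warning.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    blue = np.asarray(blue, dtype=float)
    denom = nir + 6.0 * red - 7.5 * blue + 1.0
    bad = denom == 0
    if np.any(bad):
        warnings.warn("EVI undefined where denominator == 0; returning NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, gain * (nir - red) / np.where(bad, 1.0, denom))
    return out if out.ndim else float(out)


def extract_site_values(grids: dict, sites: pd.DataFrame,
                        value_name: str = "value") -> pd.DataFrame:
    """Pull the pixel containing each site from a sequence of index grids.

    Parameters
    ----------
    grids : mapping biweek -> AsciiGrid
        Only retained (quality-passing) biweeks should be present.
    sites : DataFrame with ``id``, ``x``, ``y`` columns.

    Returns a long frame (site, biweek, value) with one row per site per
    retained biweek; a site outside a grid's extent raises an error naming
    the site.
    """
    rows = []
    for bw in sorted(grids):
        grid = grids[bw]
        for _, s in sites.iterrows():
            try:
                r, c = grid.locate(s["x"], s["y"])
            except ValueError as err:
                raise ValueError(f"site {s['id']} outside grid extent "
                                 f"(biweek {bw})") from err
            rows.append({"site": s["id"], "biweek": bw,
                         value_name: grid.values[r, c]})
    return pd.DataFrame(rows)


def loess_smooth(t, y, span: float = 0.2, degree: int = 1) -> np.ndarray:
    """Loess (locally weighted linear regression, tricube weights).

    Fits on the available (non-missing) points against the real time
    index and evaluates at every point of `t`, so gaps from discarded
    dates do not distort the local windows.  Only ``degree=1`` (local
    linear) is supported, which reproduces exactly linear inputs at any
    span.  Requires at least 4 non-missing points.
    """
    if degree != 1:
        raise NotImplementedError("only degree-1 (local linear) loess is supported")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    if ok.sum() < 4:
        raise ValueError("loess needs at least 4 non-missing points")
    out = lowess(y[ok], t[ok], frac=span, it=0, xvals=t, is_sorted=False)
    return np.asarray(out, dtype=float)


def smooth_index_series(raw: pd.DataFrame, span: float = 0.2,
                        value_name: str = "value") -> pd.DataFrame:
    """Smooth a (site, biweek, value) index frame per site with loess.

    Returns the input plus ``smoothed`` and ``flag`` columns; `flag` is
    ``observed`` where the raw value existed and ``interpolated`` where
    loess filled a retained-but-missing point.
    """
    out = []
    for site, grp in raw.groupby("site"):
        grp = grp.sort_values("biweek").copy()
        sm = loess_smooth(grp["biweek"].to_numpy(dtype=float),
                          grp[value_name].to_numpy(dtype=float), span=span)
        grp["smoothed"] = sm
        grp["flag"] = np.where(np.isfinite(grp[value_name]),
                               "observed", "interpolated")
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def index_moments(series: pd.DataFrame, axis: str = "over_sites",
                  value_col: str = "value") -> pd.DataFrame:
    """Mean/SD/kurtosis of an index series across sites or across time.

    ``over_sites`` groups by biweek (one moment row per date, the
    network-wide summary); ``over_time`` groups by site (one row per site,
    the covariates used in spatial models).  Moment definitions are those
    of :func:`gradientzi.covariates.moments`.
    """
    if axis == "over_sites":
        key = "biweek"
    elif axis == "over_time":
        key = "site"
    else:
        raise ValueError("axis must be 'over_sites' or 'over_time'")
    rows = {}
    for g, grp in series.groupby(key):
        m, s, k = _cov.moments(grp[value_col])
        rows[g] = {"mean": m, "sd": s, "kurtosis": k}
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = key
    return out
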