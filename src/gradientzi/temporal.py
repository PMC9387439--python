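"""Time-series stage: ACF/PACF, null AR model, pre-whitened
cross-correlations and lag selection.

Naively cross-correlating two autocorrelated series produces spurious
"significant" lags whenever the two share a similar autocorrelation
structure.  The guard used here is pre-whitening: fit a null
autoregressive model to the response (abundance) series, filter the
candidate covariate with the *response's* AR coefficients, and
cross-correlate the AR residuals with the filtered covariate.  Peaks that
survive identify genuine lead/lag structure.

Lag convention: **lag k means the covariate value k biweeks before the
response observation** (covariate leads).  CCFs are reported for lags
-K..K, but only covariate-leading lags 0..3 feed the lagged regression
design, since a response cannot be driven by future covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "acf", "pacf", "acf_pacf", "ARFit", "fit_ar",
    "CCFResult", "prewhiten_ccf", "select_lags", "build_lagged_design",
]


def acf(series, max_lag: int) -> np.ndarray:
    """Autocorrelation function, lags 0..max_lag.

    Complete series use the standard biased estimator (lag-k cross
    products divided by n and the lag-0 sum).  Series with missing values
    fall back to pairwise-complete averages of the products.  Raises on a
    constant series.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    ok = np.isfinite(x)
    mean = np.nanmean(x)
    z = x - mean
    var = np.nanmean(np.where(ok, z * z, np.nan))
    if not np.isfinite(var) or var == 0:
        raise ValueError("ACF undefined for constant series")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    complete = ok.all()
    for k in range(1, max_lag + 1):
        a, b = z[:-k], z[k:]
        both = np.isfinite(a) & np.isfinite(b)
        if not both.any():
            out[k] = np.nan
            continue
        if complete:
            out[k] = np.sum(a * b) / (n * var)
        else:
            out[k] = np.mean(a[both] * b[both]) / var
    return out


def pacf(series, max_lag: int) -> np.ndarray:
    """Partial ACF by the Durbin-Levinson recursion, lags 1..max_lag."""
    r = acf(series, max_lag)
    phi = np.zeros((max_lag + 1, max_lag + 1))
    out = np.empty(max_lag)
    phi[1, 1] = r[1]
    out[0] = r[1]
    for k in range(2, max_lag + 1):
        num = r[k] - np.sum(phi[k - 1, 1:k] * r[k - 1:0:-1])
        den = 1.0 - np.sum(phi[k - 1, 1:k] * r[1:k])
        phi[k, k] = num / den
        phi[k, 1:k] = phi[k - 1, 1:k] - phi[k, k] * phi[k - 1, k - 1:0:-1]
        out[k - 1] = phi[k, k]
    return out


def acf_pacf(series, max_lag: int):
    """Convenience: (ACF lags 0..K, PACF lags 1..K) for one series."""
    return acf(series, max_lag), pacf(series, max_lag)


@dataclass
class ARFit:
    """Conditional least-squares AR(p) fit.

    ``residuals`` has length ``n - order`` and is aligned with times
    ``order..n-1`` of the input; entries needing a missing lag are NaN.
    """

    order: int
    const: float
    phi: np.ndarray
    residuals: np.ndarray
    sigma2: float
    n: int

    @property
    def stable(self) -> bool:
        roots = np.roots(np.r_[1.0, -self.phi])
        return bool(np.all(np.abs(roots) < 1.0)) if self.order else True


def fit_ar(series, order: int = 1) -> ARFit:
    """Fit an AR(p) null model by conditional least squares.

    Regresses ``y_t`` on a constant and ``y_{t-1} .. y_{t-p}`` over
    complete cases.  An unstable estimate (a characteristic root on or
    inside the unit circle) warns but is returned.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= 5 * order:
        raise ValueError(f"series of length {n} too short for AR({order})")
    Xrows = np.column_stack([y[order - j - 1: n - j - 1] for j in range(order)])
    resp = y[order:]
    X = np.column_stack([np.ones(len(resp)), Xrows])
    ok = np.isfinite(resp) & np.isfinite(Xrows).all(axis=1)
    if ok.sum() <= order + 1:
        raise ValueError("too few complete cases for AR fit")
    coef, *_ = np.linalg.lstsq(X[ok], resp[ok], rcond=None)
    const, phi = coef[0], coef[1:]
    resid = resp - X[:, 1:] @ phi - const
    fit = ARFit(order=order, const=float(const), phi=phi,
                residuals=resid, sigma2=float(np.nanvar(resid)), n=n)
    if not fit.stable:
        warnings.warn(f"AR({order}) fit is unstable (|root| >= 1)")
    return fit


@dataclass
class CCFResult:
    """Cross-correlations between AR residuals and a filtered covariate.

    ``lags[i] > 0`` means the covariate leads the response by ``lags[i]``
    biweeks.  ``bound`` is the white-noise 95% limit ``1.96/sqrt(N)``.
    """

    name: str
    lags: np.ndarray
    r: np.ndarray
    bound: float
    n: int

    @property
    def significant(self) -> np.ndarray:
        return np.abs(self.r) > self.bound

    def at(self, lag: int) -> float:
        idx = np.nonzero(self.lags == lag)[0]
        if idx.size == 0:
            raise KeyError(f"lag {lag} not computed")
        return float(self.r[idx[0]])


def _ccf(a, b, max_lag: int):
    """Sample CCF of aligned arrays; positive k pairs a_t with b_{t-k}.

    Normalization follows the standard sample CCF: cross products divided
    by the series length and the overall (not per-lag) standard
    deviations.  Missing pairs are skipped.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    za = a - np.nanmean(a)
    zb = b - np.nanmean(b)
    sa = np.sqrt(np.nanmean(za ** 2))
    sb = np.sqrt(np.nanmean(zb ** 2))
    if sa == 0 or sb == 0:
        raise ValueError("CCF undefined for constant series")
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            x, yv = za[k:], zb[: n - k] if k else zb
        else:
            x, yv = za[: n + k], zb[-k:]
        both = np.isfinite(x) & np.isfinite(yv)
        r[i] = np.sum(x[both] * yv[both]) / (n * sa * sb)
    return lags, r


def prewhiten_ccf(response, covariate, ar_fit: ARFit | None = None,
                  max_lag: int = 10, name: str = "covariate") -> CCFResult:
    """Pre-whitened cross-correlation between a response and a covariate.

    The covariate is filtered with the response's AR coefficients,
    ``x'_t = x_t - sum_i phi_i x_{t-i}``, and cross-correlated with the
    response's AR residuals.  With ``phi = 0`` the filter is the
    identity.  `ar_fit` defaults to an AR(1) fit of the response.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if len(y) != len(x):
        raise ValueError("response and covariate must be aligned (same length)")
    if ar_fit is None:
        ar_fit = fit_ar(y, order=1)
    p = ar_fit.order
    if ar_fit.n != len(y):
        raise ValueError("ar_fit was estimated on a series of different length")
    xf = x[p:].copy()
    for j, ph in enumerate(ar_fit.phi, start=1):
        xf = xf - ph * x[p - j: len(x) - j]
    lags, r = _ccf(ar_fit.residuals, xf, max_lag)
    n_eff = len(xf)
    return CCFResult(name=name, lags=lags, r=r,
                     bound=float(stats.norm.ppf(0.975) / np.sqrt(n_eff)),
                     n=n_eff)


def select_lags(ccfs: dict, max_lead: int = 3) -> pd.DataFrame:
    """Choose, per covariate, the leading lag (0..max_lead) with max |r|.

    Only lags whose correlation exceeds the white-noise bound are
    eligible; covariates with no significant leading lag are dropped.
    Ties in |r| go to the smaller lag.
    """
    rows = []
    for nm, ccf in ccfs.items():
        best = None
        for k in range(0, max_lead + 1):
            try:
                rk = ccf.at(k)
            except KeyError:
                continue
            if abs(rk) <= ccf.bound:
                continue
            if best is None or abs(rk) > abs(best[1]):
                best = (k, rk)
        if best is not None:
            rows.append({"covariate": nm, "lag": best[0], "r": best[1]})
    return pd.DataFrame(rows, columns=["covariate", "lag", "r"])


def build_lagged_design(panel: pd.DataFrame, selection: pd.DataFrame,
                        response: str, max_lag: int = 3,
                        ar_term: bool = True, zero_covariates=("water_temp",),
                        weights_col: str | None = None) -> pd.DataFrame:
    """Assemble the model-ready lagged design table.

    `panel` is a biweek-indexed frame holding the response, the candidate
    covariates and (optionally) contemporaneous zero-part covariates and
    a weights column.  The first `max_lag` rows are dropped so every
    selected lag is available.  Columns are named ``{covariate}_lag{k}``;
    the lag-1 response enters as ``ar1`` when `ar_term`.
    """
    panel = panel.sort_index()
    n = len(panel)
    out = pd.DataFrame(index=panel.index[max_lag:])
    out[response] = panel[response].iloc[max_lag:].to_numpy()
    if ar_term:
        out["ar1"] = panel[response].shift(1).iloc[max_lag:].to_numpy()
    for _, row in selection.iterrows():
        nm, k = row["covariate"], int(row["lag"])
        out[f"{nm}_lag{k}"] = panel[nm].shift(k).iloc[max_lag:].to_numpy()
    for zc in zero_covariates:
        if zc in panel.columns:
            out[zc] = panel[zc].iloc[max_lag:].to_numpy()
    if weights_col is not None and weights_col in panel.columns:
        out[weights_col] = panel[weights_col].iloc[max_lag:].to_numpy()
    assert len(out) == n - max_lag
    return out
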