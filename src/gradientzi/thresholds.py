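"""WTp50 — the water-temperature threshold for structural zeros.

With a zero-inflation part ``logit(pi) = a + b * WT`` (water temperature,
deg C), the threshold WTp50 solves ``a + b * WTp50 = 0``: the temperature
at which a zero is equally likely to be structural (unsuitable habitat)
or a draw from the count process.  Below WTp50 (for b < 0) a zero most
likely reflects adverse thermal conditions; above it, ordinary
population dynamics.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["wtp50", "wtp50_se", "wtp50_from_fit", "classify_zero"]


def wtp50(intercept: float, slope: float) -> float:
    """Solve ``intercept + slope * WTp50 = 0`` for the threshold (deg C).

    The structural-zero probability at the returned temperature is
    exactly 0.5.  A zero slope leaves the threshold undefined.
    """
    if slope == 0:
        raise ZeroDivisionError("WTp50 undefined when the temperature "
                                "coefficient is zero")
    return -float(intercept) / float(slope)


def wtp50_se(gamma, cov) -> float:
    """Delta-method standard error of ``-a/b`` (deg C).

    `gamma` is ``(a, b)`` — zero-part intercept and temperature slope —
    and `cov` their 2x2 covariance.  First-order expansion:
    ``grad = (-1/b, a/b**2)``, ``SE = sqrt(grad @ cov @ grad)``.  A
    non-finite or negative quadratic form yields NaN with a warning.
    """
    a, b = (float(v) for v in gamma)
    if b == 0:
        raise ZeroDivisionError("WTp50 undefined when the temperature "
                                "coefficient is zero")
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("cov must be 2x2")
    grad = np.array([-1.0 / b, a / b ** 2])
    var = float(grad @ cov @ grad)
    if not np.isfinite(var) or var < 0:
        warnings.warn("invalid covariance; WTp50 SE undefined")
        return float("nan")
    return float(np.sqrt(var))


def wtp50_from_fit(fit, temp_term: str = "water_temp"):
    """(WTp50, SE) from a fitted zero-inflated model.

    The zero part must be ``Intercept + temp_term``; the SE uses the
    fit's zero-block covariance via the delta method.
    """
    a = fit.coef("zero", "Intercept")
    b = fit.coef("zero", temp_term)
    est = wtp50(a, b)
    zc = fit.zero_vcov()
    idx = [0, 1 + fit.zero_terms.index(temp_term)]
    se = wtp50_se((a, b), zc[np.ix_(idx, idx)])
    return est, se


def classify_zero(water_temp, threshold: float, slope_negative: bool = True):
    """Label a zero count as 'structural' or 'sampling' relative to WTp50.

    Purely a reporting convenience: with a negative temperature slope,
    zeros below the threshold are most likely structural (adverse
    conditions), zeros above it sampling zeros from the count process.
    """
    wt = np.asarray(water_temp, dtype=float)
    below = wt < threshold if slope_negative else wt > threshold
    out = np.where(below, "structural", "sampling")
    return out if out.ndim else str(out)
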