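"""Zero-inflated Poisson / negative-binomial count regression.

The abundance models are two-part mixtures: a Bernoulli "structural zero"
component with probability ``pi = logistic(z @ gamma)`` (unsuitable
habitat — the trap was never colonisable) and a count component with mean
``lam = exp(x @ beta)`` that is Poisson or negative binomial (NB2: mean
``lam``, size ``theta``, variance ``lam + lam**2/theta``; the size is
reported as "overdispersion").  Observed zeros are a mixture of the two
sources:

    P(Y=0) = pi + (1 - pi) * f(0; lam, theta)
    P(Y=y) = (1 - pi) * f(y; lam, theta)          for y > 0

Fitting is by maximum likelihood: quasi-Newton (BFGS) with an analytic
gradient, started from a Poisson GLM on the positive counts (count part)
and a logistic regression on the zero indicator (zero part).  ``theta``
is estimated on the log scale to stay positive.  The covariance matrix is
the inverse observed information; count-part inference is Wald (normal z),
and likelihood-ratio chi-square tests are available for zero-part terms.

Observation weights are frequency-style multipliers on the per-observation
log-likelihood contributions by default (each row counts as ``w`` traps);
an exposure-offset alternative (``lam = w * exp(x @ beta)``) is available
via ``weights_mode="offset"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from statsmodels.tools import numdiff

__all__ = [
    "ZeroInflatedCountRegressor",
    "ZICountFit",
    "SelectionTrace",
    "zi_loglik",
    "fit_zicount",
    "abundance_change",
    "percent_change",
    "structural_zero_prob",
    "backward_eliminate",
    "zero_part_lr_tests",
]

_FAMILIES = ("poisson", "negbin")


def _split_params(params, kx, kz, family):
    beta = params[:kx]
    gamma = params[kx:kx + kz]
    log_theta = params[kx + kz] if family == "negbin" else None
    return beta, gamma, log_theta


def _log_pmf(y, log_lam, theta):
    """Elementwise log count pmf (Poisson when theta is None, else NB2)."""
    lam = np.exp(log_lam)
    if theta is None:
        return y * log_lam - lam - special.gammaln(y + 1.0)
    log_ratio = np.log(theta) - np.log(theta + lam)
    return (special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * log_ratio + y * (log_lam - np.log(theta + lam)))


def zi_loglik(params, y, X, Z, family="poisson", weights=None,
              weights_mode="frequency"):
    """Weighted log-likelihood of a zero-inflated count model.

    ``params`` packs ``[beta, gamma]`` (plus ``log(theta)`` last for the
    negative binomial).  For ``y == 0`` the contribution is
    ``log(pi + (1-pi) f(0))``; for ``y > 0`` it is
    ``log(1-pi) + log f(y)``.  Frequency weights multiply contributions;
    offset weights scale the count mean instead.
    """
    y = np.asarray(y)
    if not np.allclose(y, np.round(y)) or np.any(y < 0):
        raise ValueError("counts must be nonnegative integers")
    ll, _ = _ll_terms(params, y.astype(float), np.asarray(X, float),
                      np.asarray(Z, float), family, weights, weights_mode,
                      want_grad=False)
    return float(ll)


def _ll_terms(params, y, X, Z, family, weights, weights_mode, want_grad=True):
    # extreme parameter values visited during line searches overflow exp();
    # the resulting -inf/nan objective values steer the optimizer away on
    # their own, so the warnings are noise
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _ll_terms_impl(params, y, X, Z, family, weights, weights_mode,
                              want_grad)


def _ll_terms_impl(params, y, X, Z, family, weights, weights_mode, want_grad):
    kx, kz = X.shape[1], Z.shape[1]
    beta, gamma, log_theta = _split_params(np.asarray(params, float), kx, kz, family)
    theta = np.exp(log_theta) if log_theta is not None else None
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)

    eta_c = X @ beta
    if weights_mode == "offset":
        eta_c = eta_c + np.log(np.maximum(w, 1e-300))
    eta_z = Z @ gamma
    lam = np.exp(eta_c)
    # log pi / log(1-pi) via stable softplus
    log_pi = -np.logaddexp(0.0, -eta_z)
    log_1mpi = -np.logaddexp(0.0, eta_z)

    is0 = y == 0
    logp = _log_pmf(y, eta_c, theta)
    ll_obs = np.where(is0,
                      np.logaddexp(log_pi, log_1mpi + logp),
                      log_1mpi + logp)
    wc = np.ones_like(y) if weights_mode == "offset" or weights is None else w
    ll = np.sum(wc * ll_obs)
    if not want_grad:
        return ll, None

    pi = special.expit(eta_z)
    if theta is None:
        dc_pos = y - lam                      # d ll / d eta_c for y>0
        dlogp0_dlam_lam = -lam                # lam * d log f(0)/d lam
    else:
        dc_pos = (y - lam) * theta / (theta + lam)
        dlogp0_dlam_lam = -theta * lam / (theta + lam)

    # y == 0 ratios, computed in log space for stability
    r0 = np.exp(log_1mpi + logp - ll_obs)     # (1-pi) f(0) / P(0)
    rpi = np.exp(log_pi - ll_obs)             # pi / P(0)
    p0 = np.exp(logp)
    dz = np.where(is0, rpi * (1.0 - pi) * (1.0 - p0), -pi)
    dc = np.where(is0, r0 * dlogp0_dlam_lam, dc_pos)

    gb = X.T @ (wc * dc)
    gg = Z.T @ (wc * dz)
    grads = [gb, gg]
    if theta is not None:
        lr = np.log(theta) - np.log(theta + lam)
        dth_pos = (special.digamma(y + theta) - special.digamma(theta)
                   + lr + 1.0 - (theta + y) / (theta + lam))
        dth0 = lr + 1.0 - theta / (theta + lam)
        dth = np.where(is0, r0 * dth0, dth_pos)
        grads.append(np.array([np.sum(wc * dth) * theta]))  # chain to log theta
    return ll, np.concatenate(grads)


def _check_full_rank(M, names, part):
    if M.shape[0] < M.shape[1] or np.linalg.matrix_rank(M) < M.shape[1]:
        _, R = np.linalg.qr(M)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.where(diag < 1e-8 * max(diag.max(), 1))[0]]
        raise ValueError(f"{part} design matrix is rank deficient; "
                         f"collinear column(s): {bad or names}")


class ZeroInflatedCountRegressor(BaseEstimator):
    """Zero-inflated count regression (scikit-learn style).

    Parameters
    ----------
    family : {"poisson", "negbin"}
        Count component; "negbin" estimates the NB2 size ``theta``.
    fit_intercept : bool
        Prepend an intercept column to both design matrices.
    weights_mode : {"frequency", "offset"}
        How ``sample_weight`` enters: log-likelihood multiplier (default)
        or exposure offset on the count mean.
    tol : float
        Gradient-norm convergence tolerance for BFGS.
    maxiter : int
        Iteration cap; non-convergence sets ``converged_ = False`` and
        warns rather than raising.

    Attributes (after ``fit``)
    --------------------------
    coef_count_, coef_zero_ : ndarray — log-link count coefficients and
        logit-link zero-inflation coefficients (intercept first when
        ``fit_intercept``).
    theta_ : float or None — NB2 size ("overdispersion").
    vcov_ : ndarray — joint covariance (inverse observed information),
        ordered [beta, gamma(, log theta)].
    loglik_, aic_, n_obs_, converged_ : fit summaries; ``aic_`` is
        ``2k - 2 loglik`` with k the number of free parameters.
    se_, zvalues_, pvalues_ : Wald summaries over the packed parameter
        vector (theta's SE is delta-method transformed to the theta scale).
    """

    def __init__(self, family="poisson", fit_intercept=True,
                 weights_mode="frequency", tol=1e-8, maxiter=500):
        self.family = family
        self.fit_intercept = fit_intercept
        self.weights_mode = weights_mode
        self.tol = tol
        self.maxiter = maxiter

    # -- helpers -----------------------------------------------------------
    def _design(self, X, fitting=False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X

    def _starts(self, y, X, Z, w):
        import statsmodels.api as sm
        beta = np.zeros(X.shape[1])
        pos = y > 0
        try:
            if pos.sum() >= X.shape[1] + 1:
                glm = sm.GLM(y[pos], X[pos], family=sm.families.Poisson(),
                             freq_weights=w[pos])
                beta = glm.fit().params
            else:
                raise ValueError
        except Exception:
            mean = max(np.average(y, weights=w), 1e-3)
            beta[0] = np.log(mean)
        gamma = np.zeros(Z.shape[1])
        try:
            glm = sm.GLM((y == 0).astype(float), Z,
                         family=sm.families.Binomial(), freq_weights=w)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gamma = np.clip(glm.fit(maxiter=50).params, -5, 5)
        except Exception:
            pass
        params = [beta, gamma]
        if self.family == "negbin":
            mu = max(np.average(y, weights=w), 1e-3)
            var = max(np.average((y - mu) ** 2, weights=w), mu + 1e-3)
            theta0 = np.clip(mu ** 2 / max(var - mu, 1e-3), 0.1, 50.0)
            params.append([np.log(theta0)])
        return np.concatenate([np.asarray(p, float) for p in params])

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, X_zero=None, sample_weight=None):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.weights_mode not in ("frequency", "offset"):
            raise ValueError("weights_mode must be 'frequency' or 'offset'")
        y = np.asarray(y, dtype=float).ravel()
        if not np.allclose(y, np.round(y)) or np.any(y < 0):
            raise ValueError("counts must be nonnegative integers")
        if not np.any(y > 0):
            raise ValueError("need at least one positive count")
        Xd = self._design(X)
        Zd = self._design(X_zero if X_zero is not None else np.empty((len(y), 0)))
        if Zd.shape[1] == 0:
            raise ValueError("zero part needs at least an intercept")
        _check_full_rank(Xd, [f"x{j}" for j in range(Xd.shape[1])], "count")
        _check_full_rank(Zd, [f"z{j}" for j in range(Zd.shape[1])], "zero")
        w = (np.ones_like(y) if sample_weight is None
             else np.asarray(sample_weight, dtype=float).ravel())
        if len(w) != len(y):
            raise ValueError("sample_weight length must match y")

        x0 = self._starts(y, Xd, Zd, w)

        def negll(p):
            ll, _ = _ll_terms(p, y, Xd, Zd, self.family, w, self.weights_mode,
                              want_grad=False)
            return -ll

        def neggrad(p):
            _, g = _ll_terms(p, y, Xd, Zd, self.family, w, self.weights_mode)
            return -g

        res = optimize.minimize(negll, x0, jac=neggrad, method="BFGS",
                                options={"gtol": self.tol,
                                         "maxiter": self.maxiter})
        if not res.success:
            # polish with a tighter Newton-CG pass before giving up
            res2 = optimize.minimize(negll, res.x, jac=neggrad, method="BFGS",
                                     options={"gtol": self.tol * 100,
                                              "maxiter": self.maxiter})
            if res2.fun <= res.fun:
                res = res2
        self.converged_ = bool(np.linalg.norm(neggrad(res.x), np.inf)
                               < max(self.tol * 100, 1e-4))
        if not self.converged_:
            warnings.warn("zero-inflated fit did not converge; "
                          "results flagged via converged_=False")

        kx, kz = Xd.shape[1], Zd.shape[1]
        self.params_ = res.x
        beta, gamma, log_theta = _split_params(res.x, kx, kz, self.family)
        self.coef_count_ = beta
        self.coef_zero_ = gamma
        self.theta_ = float(np.exp(log_theta)) if log_theta is not None else None
        self.loglik_ = float(-res.fun)
        k = len(res.x)
        self.n_params_ = k
        self.aic_ = 2.0 * k - 2.0 * self.loglik_
        self.n_obs_ = len(y)

        H = numdiff.approx_hess1(res.x, negll)
        H = (H + H.T) / 2.0
        try:
            vcov = np.linalg.inv(H)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
            warnings.warn("observed information singular; vcov from pseudoinverse")
        self.vcov_ = vcov
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
        self.se_ = se
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues_ = res.x / se
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.zvalues_))
        if self.theta_ is not None:
            # delta method: SE(theta) = theta * SE(log theta)
            self.se_theta_ = float(self.theta_ * se[-1])
        self._kx, self._kz = kx, kz
        return self

    def predict(self, X, X_zero=None, sample_weight=None):
        """Expected count ``(1 - pi) * lam`` (times exposure in offset mode)."""
        Xd = self._design(X)
        Zd = self._design(X_zero if X_zero is not None
                          else np.empty((Xd.shape[0], 0)))
        lam = np.exp(Xd @ self.coef_count_)
        if self.weights_mode == "offset" and sample_weight is not None:
            lam = lam * np.asarray(sample_weight, float)
        pi = special.expit(Zd @ self.coef_zero_)
        return (1.0 - pi) * lam

    def structural_zero_prob(self, X_zero):
        """Probability of a structural zero, ``logistic(z @ gamma)``."""
        Zd = self._design(X_zero)
        return special.expit(Zd @ self.coef_zero_)


# ---------------------------------------------------------------------------
# formula-level interface


@dataclass
class ZICountFit:
    """A fitted zero-inflated model with named coefficients.

    ``summary`` is a tidy frame with one row per coefficient: part
    ("count" or "zero"), term, estimate, se, z, p and — for count terms —
    the multiplicative abundance change ``exp(estimate)`` per unit
    increase of the covariate.
    """

    family: str
    response: str
    count_terms: list
    zero_terms: list
    summary: pd.DataFrame
    theta: float | None
    se_theta: float | None
    vcov: np.ndarray
    loglik: float
    aic: float
    n: int
    converged: bool
    model: ZeroInflatedCountRegressor = field(repr=False)

    def coef(self, part: str, term: str) -> float:
        s = self.summary
        row = s[(s["part"] == part) & (s["term"] == term)]
        if row.empty:
            raise KeyError(f"no {part}-part term {term!r}")
        return float(row["estimate"].iloc[0])

    def zero_vcov(self) -> np.ndarray:
        """Covariance block of the zero-inflation coefficients."""
        kx = self.model._kx
        kz = self.model._kz
        return self.vcov[kx:kx + kz, kx:kx + kz]

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "response": self.response,
            "count_terms": list(self.count_terms),
            "zero_terms": list(self.zero_terms),
            "coefficients": self.summary.to_dict(orient="records"),
            "theta": self.theta,
            "se_theta": self.se_theta,
            "vcov": np.asarray(self.vcov).tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "converged": self.converged,
        }
        return json.dumps(payload, indent=1)


def _design_from(data: pd.DataFrame, terms, part: str) -> np.ndarray:
    missing = [t for t in terms if t not in data.columns]
    if missing:
        raise ValueError(f"{part}-part covariate(s) not in data: {missing}")
    return data[list(terms)].to_numpy(dtype=float)


def fit_zicount(data: pd.DataFrame, response: str, count_terms, zero_terms,
                family: str = "poisson", weights=None,
                weights_mode: str = "frequency", **kwargs) -> ZICountFit:
    """Fit a zero-inflated model from named columns of a data frame.

    `count_terms` / `zero_terms` are column names (an intercept is always
    added to each part).  `weights` may be a column name or an array.
    """
    y = data[response].to_numpy(dtype=float)
    X = _design_from(data, count_terms, "count")
    Z = _design_from(data, zero_terms, "zero")
    if isinstance(weights, str):
        weights = data[weights].to_numpy(dtype=float)
    est = ZeroInflatedCountRegressor(family=family, weights_mode=weights_mode,
                                     **kwargs)
    est.fit(X, y, X_zero=Z, sample_weight=weights)

    names_c = ["Intercept"] + list(count_terms)
    names_z = ["Intercept"] + list(zero_terms)
    rows = []
    idx = 0
    for nm, b in zip(names_c, est.coef_count_):
        rows.append({"part": "count", "term": nm, "estimate": b,
                     "se": est.se_[idx], "z": est.zvalues_[idx],
                     "p": est.pvalues_[idx],
                     "abundance_change": abundance_change(b)})
        idx += 1
    for nm, g in zip(names_z, est.coef_zero_):
        rows.append({"part": "zero", "term": nm, "estimate": g,
                     "se": est.se_[idx], "z": est.zvalues_[idx],
                     "p": est.pvalues_[idx], "abundance_change": np.nan})
        idx += 1
    summary = pd.DataFrame(rows)
    return ZICountFit(family=family, response=response,
                      count_terms=list(count_terms), zero_terms=list(zero_terms),
                      summary=summary, theta=est.theta_,
                      se_theta=getattr(est, "se_theta_", None),
                      vcov=est.vcov_, loglik=est.loglik_, aic=est.aic_,
                      n=est.n_obs_, converged=est.converged_, model=est)


def abundance_change(coef: float) -> float:
    """Multiplicative abundance change per unit covariate increase, exp(coef)."""
    with np.errstate(over="ignore"):
        return float(np.exp(coef))


def percent_change(coef: float) -> float:
    """Percent abundance change per unit increase, ``100*(exp(coef)-1)``."""
    return 100.0 * (np.exp(coef) - 1.0)


def structural_zero_prob(gamma, z):
    """``logistic(gamma . [1, z])`` — structural-zero probability.

    `gamma` holds the zero-part coefficients (intercept first); `z` the
    covariate values without the intercept.
    """
    gamma = np.asarray(gamma, dtype=float)
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.ndim == 1 and len(gamma) == len(z) + 1:
        z = z.reshape(-1, 1) if len(gamma) == 2 else z.reshape(1, -1)
    zz = np.column_stack([np.ones(z.shape[0]), z])
    if zz.shape[1] != len(gamma):
        raise ValueError(f"expected {len(gamma) - 1} zero-part covariate(s), "
                         f"got {zz.shape[1] - 1}")
    out = special.expit(zz @ gamma)
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionTrace:
    """Backward-elimination audit trail: one row per accepted round."""

    steps: pd.DataFrame            # columns: round, dropped, aic, count_terms
    final: ZICountFit

    @property
    def aic_path(self):
        return self.steps["aic"].to_list()


def backward_eliminate(data: pd.DataFrame, response: str, count_terms,
                       zero_terms, family: str = "poisson", weights=None,
                       weights_mode: str = "frequency",
                       eliminate_zero: bool = False, **kwargs) -> SelectionTrace:
    """AIC backward elimination of count-part terms.

    Each round refits the model with every single term removed and drops
    the term whose removal gives the lowest AIC; stops when no removal
    improves (lowers) AIC.  AIC ties below 1e-8 are broken by dropping
    the term listed later in the formula.  Zero-part terms are only
    eligible when ``eliminate_zero=True``.  A candidate whose fit fails
    is skipped with a warning.
    """
    count_terms = list(count_terms)
    zero_terms = list(zero_terms)
    current = fit_zicount(data, response, count_terms, zero_terms,
                          family=family, weights=weights,
                          weights_mode=weights_mode, **kwargs)
    rows = [{"round": 0, "dropped": None, "aic": current.aic,
             "count_terms": "+".join(count_terms),
             "zero_terms": "+".join(zero_terms)}]
    rnd = 0
    while True:
        candidates = [("count", t) for t in count_terms]
        if eliminate_zero:
            candidates += [("zero", t) for t in zero_terms]
        best = None  # (aic, order_index, part, term, fit)
        for order, (part, term) in enumerate(candidates):
            ct = [t for t in count_terms if not (part == "count" and t == term)]
            zt = [t for t in zero_terms if not (part == "zero" and t == term)]
            try:
                cand = fit_zicount(data, response, ct, zt, family=family,
                                   weights=weights, weights_mode=weights_mode,
                                   **kwargs)
            except Exception as err:  # noqa: BLE001 - candidate failures logged
                warnings.warn(f"candidate drop {part}:{term} failed: {err}")
                continue
            # later-listed term wins ties (larger order index preferred)
            if (best is None or cand.aic < best[0] - 1e-8
                    or (abs(cand.aic - best[0]) <= 1e-8 and order > best[1])):
                best = (cand.aic, order, part, term, cand)
        if best is None or best[0] >= current.aic - 1e-8:
            break
        rnd += 1
        _, _, part, term, current = best
        if part == "count":
            count_terms.remove(term)
        else:
            zero_terms.remove(term)
        rows.append({"round": rnd, "dropped": f"{part}:{term}",
                     "aic": current.aic, "count_terms": "+".join(count_terms),
                     "zero_terms": "+".join(zero_terms)})
    return SelectionTrace(steps=pd.DataFrame(rows), final=current)


def zero_part_lr_tests(data: pd.DataFrame, fit: ZICountFit, weights=None,
                       weights_mode: str = "frequency") -> pd.DataFrame:
    """Likelihood-ratio chi-square tests for each zero-part term.

    Refits the model with the term removed; the statistic is
    ``2*(loglik_full - loglik_reduced)`` on 1 df.  The intercept-only
    zero part is tested against a model with the zero probability's
    intercept pushed to the no-inflation limit is not attempted; only
    named covariates are tested.
    """
    rows = []
    for term in fit.zero_terms:
        reduced_terms = [t for t in fit.zero_terms if t != term]
        reduced = fit_zicount(data, fit.response, fit.count_terms,
                              reduced_terms, family=fit.family,
                              weights=weights, weights_mode=weights_mode)
        chi2 = max(2.0 * (fit.loglik - reduced.loglik), 0.0)
        rows.append({"term": term, "chi2": chi2, "df": 1,
                     "p": float(stats.chi2.sf(chi2, 1))})
    return pd.DataFrame(rows)
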