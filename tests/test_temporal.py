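"""ACF/PACF, AR null models, pre-whitened CCFs and lag selection."""

import numpy as np
import pandas as pd
import pytest

from gradientzi.temporal import (
    CCFResult,
    acf,
    acf_pacf,
    build_lagged_design,
    fit_ar,
    pacf,
    prewhiten_ccf,
    select_lags,
)


def simulate_ar1(phi, n, rng, sigma=1.0):
    x = np.zeros(n)
    eps = rng.normal(0, sigma, n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


class TestAcfPacf:
    def test_ar1_acf_matches_phi(self, rng):
        x = simulate_ar1(0.7, 10_000, rng)
        r = acf(x, 5)
        assert r[0] == 1.0
        assert r[1] == pytest.approx(0.7, abs=0.02)
        assert r[2] == pytest.approx(0.49, abs=0.03)

    def test_white_noise_acf_small(self, rng):
        x = rng.normal(size=10_000)
        r = acf(x, 5)
        assert np.all(np.abs(r[1:]) < 0.03)

    def test_pacf_of_ar1_cuts_off_after_lag_one(self, rng):
        x = simulate_ar1(0.6, 10_000, rng)
        p = pacf(x, 4)
        assert p[0] == pytest.approx(0.6, abs=0.03)
        assert abs(p[1]) < 0.05 and abs(p[2]) < 0.05

    def test_matches_statsmodels_on_complete_series(self, rng):
        """Independent reference: statsmodels' biased ACF and L-D PACF."""
        from statsmodels.tsa.stattools import acf as sm_acf, pacf as sm_pacf
        x = simulate_ar1(0.5, 300, rng)
        np.testing.assert_allclose(acf(x, 8), sm_acf(x, nlags=8, fft=False),
                                   atol=1e-10)
        np.testing.assert_allclose(pacf(x, 8),
                                   sm_pacf(x, nlags=8, method="ldb")[1:],
                                   atol=1e-8)

    def test_missing_values_pairwise_complete(self, rng):
        x = simulate_ar1(0.7, 2000, rng)
        xm = x.copy()
        xm[rng.choice(2000, 200, replace=False)] = np.nan
        r = acf(xm, 3)
        assert r[1] == pytest.approx(0.7, abs=0.07)

    def test_constant_series_error(self):
        with pytest.raises(ValueError, match="constant"):
            acf(np.ones(50), 3)

    def test_series_too_short_error(self):
        with pytest.raises(ValueError, match="short"):
            acf_pacf(np.arange(5.0), 5)


class TestFitAr:
    def test_recovers_phi_within_3se(self, rng):
        x = simulate_ar1(0.5, 400, rng)
        fit = fit_ar(x, order=1)
        se = np.sqrt((1 - 0.5 ** 2) / 400)  # asymptotic SE of phi-hat
        assert abs(fit.phi[0] - 0.5) < 3 * se

    def test_residuals_are_whitened(self, rng):
        x = simulate_ar1(0.8, 5000, rng)
        fit = fit_ar(x, order=1)
        assert abs(acf(fit.residuals, 1)[1]) < 0.05

    def test_residual_length_is_n_minus_order(self, rng):
        x = simulate_ar1(0.4, 100, rng)
        for order in (1, 2, 3):
            assert len(fit_ar(x, order).residuals) == 100 - order

    def test_short_series_error(self):
        with pytest.raises(ValueError):
            fit_ar(np.arange(5.0), order=1)

    def test_unstable_fit_warns_not_raises(self, rng):
        x = np.empty(120)
        x[0] = 1.0
        for t in range(1, 120):  # explosive AR, |phi| > 1
            x[t] = 1.06 * x[t - 1] + rng.normal(0, 0.01)
        with pytest.warns(UserWarning, match="unstable"):
            fit_ar(x, order=1)


def brute_ccf(a, b, k, n, sa, sb):
    """Explicit-loop oracle for the standard sample CCF at lag k
    (positive k: b leads a by k steps)."""
    total = 0.0
    za = a - np.mean(a)
    zb = b - np.mean(b)
    for t in range(len(a)):
        if 0 <= t - k < len(b):
            total += za[t] * zb[t - k]
    return total / (n * sa * sb)


class TestPrewhitenCcf:
    def test_ccf_agrees_with_explicit_loop_oracle(self, rng):
        a = rng.normal(size=80)
        b = rng.normal(size=80)
        from gradientzi.temporal import _ccf
        lags, r = _ccf(a, b, 5)
        sa, sb = np.std(a), np.std(b)
        for k, rk in zip(lags, r):
            assert rk == pytest.approx(brute_ccf(a, b, k, 80, sa, sb),
                                       abs=1e-12)

    def test_ccf_close_to_shifted_pearson_for_long_series(self, rng):
        a = rng.normal(size=5000)
        b = np.roll(a, 2) + rng.normal(0, 0.5, 5000)
        from gradientzi.temporal import _ccf
        _, r = _ccf(a, b, 3)
        # b trails a by 2 steps, so the covariate-lagging lag -2 pairs
        # a_t with b_{t+2} = a_t
        pear = np.corrcoef(a[:-2], b[2:])[0, 1]
        k_idx = np.nonzero(np.arange(-3, 4) == -2)[0][0]
        # overall-SD normalization vs per-lag Pearson: O(1/n) apart
        assert r[k_idx] == pytest.approx(pear, abs=0.01)

    def test_covariate_equal_to_response_peaks_at_zero(self, rng):
        y = simulate_ar1(0.6, 500, rng)
        res = prewhiten_ccf(y, y, max_lag=5)
        assert res.at(0) == pytest.approx(1.0, abs=0.05)

    def test_phi_zero_is_identity_filter(self, rng):
        y = rng.normal(size=200)
        x = rng.normal(size=200)
        ar = fit_ar(y, order=1)
        ar.phi = np.array([0.0])
        ar.residuals = y[1:] - np.mean(y[1:])
        res = prewhiten_ccf(y, x, ar_fit=ar, max_lag=4)
        from gradientzi.temporal import _ccf
        _, r_direct = _ccf(y[1:] - np.mean(y[1:]), x[1:], 4)
        np.testing.assert_allclose(res.r, r_direct, atol=1e-10)

    def test_constructed_lag2_effect_peaks_at_lag2(self, rng):
        x = simulate_ar1(0.5, 600, rng)
        noise = rng.normal(0, 0.5, 600)
        y = np.empty(600)
        y[2:] = x[:-2] + noise[2:]
        y[:2] = noise[:2]
        res = prewhiten_ccf(y, x, max_lag=6, name="x")
        lead_r = {k: abs(res.at(k)) for k in range(0, 4)}
        assert max(lead_r, key=lead_r.get) == 2
        assert res.at(2) > res.bound

    def test_misaligned_series_error(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            prewhiten_ccf(rng.normal(size=50), rng.normal(size=49))

    def test_independent_white_series_rarely_exceed_bounds(self, rng):
        exceed = []
        for _ in range(300):
            y = rng.normal(size=300)
            x = rng.normal(size=300)
            res = prewhiten_ccf(y, x, max_lag=3)
            exceed.extend(np.abs(res.r) > res.bound)
        rate = np.mean(exceed)
        assert 0.02 < rate < 0.08  # nominal 5% false-positive rate


class TestSelectLags:
    def _ccf(self, name, rs, bound=0.2):
        lags = np.arange(-3, 4)
        return CCFResult(name=name, lags=lags, r=np.asarray(rs, float),
                         bound=bound, n=50)

    def test_single_significant_peak_at_lag_three(self):
        res = self._ccf("wt_kurt", [0, 0, 0, 0.05, 0.1, 0.15, 0.45])
        sel = select_lags({"wt_kurt": res})
        assert sel.iloc[0]["lag"] == 3

    def test_no_significant_lag_drops_covariate(self):
        res = self._ccf("dull", [0.1, 0, 0.05, 0.1, 0.1, 0.15, 0.1])
        assert len(select_lags({"dull": res})) == 0

    def test_tie_prefers_smaller_lag(self):
        res = self._ccf("tied", [0, 0, 0, 0.4, 0, 0.4, 0])
        sel = select_lags({"tied": res})
        assert sel.iloc[0]["lag"] == 0

    def test_negative_lags_never_selected(self):
        # huge correlation at covariate-lagging side must be ignored
        res = self._ccf("future", [0.9, 0, 0, 0.25, 0, 0, 0])
        sel = select_lags({"future": res})
        assert sel.iloc[0]["lag"] == 0 and sel.iloc[0]["r"] == 0.25


class TestBuildLaggedDesign:
    def _panel(self, n=51, rng=None):
        rng = rng or np.random.default_rng(0)
        return pd.DataFrame({
            "y": rng.poisson(2, n), "cov": rng.normal(size=n),
            "water_temp": rng.normal(15, 5, n),
            "n_wet": rng.integers(20, 28, n).astype(float),
        }, index=pd.RangeIndex(n, name="biweek"))

    def test_51_biweeks_max_lag_3_gives_48_rows(self):
        panel = self._panel(51)
        sel = pd.DataFrame({"covariate": ["cov"], "lag": [2], "r": [0.4]})
        out = build_lagged_design(panel, sel, "y", max_lag=3,
                                  weights_col="n_wet")
        assert len(out) == 48
        assert {"y", "ar1", "cov_lag2", "water_temp", "n_wet"} <= \
            set(out.columns)

    def test_lagged_column_is_shifted_covariate(self):
        panel = self._panel(20)
        sel = pd.DataFrame({"covariate": ["cov"], "lag": [2], "r": [0.4]})
        out = build_lagged_design(panel, sel, "y", max_lag=3)
        np.testing.assert_allclose(out["cov_lag2"].to_numpy(),
                                   panel["cov"].to_numpy()[1:-2])

    def test_all_zero_lags_reproduce_original_covariates(self):
        panel = self._panel(30)
        sel = pd.DataFrame({"covariate": ["cov"], "lag": [0], "r": [0.4]})
        out = build_lagged_design(panel, sel, "y", max_lag=0, ar_term=False)
        np.testing.assert_array_equal(out["cov_lag0"].to_numpy(),
                                      panel["cov"].to_numpy())
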