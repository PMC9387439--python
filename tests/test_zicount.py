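"""Zero-inflated count engine: likelihood, fitting, inference, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gradientzi.zicount import (
    ZeroInflatedCountRegressor,
    abundance_change,
    backward_eliminate,
    fit_zicount,
    percent_change,
    structural_zero_prob,
    zero_part_lr_tests,
    zi_loglik,
)


def _pack(beta, gamma, log_theta=None):
    parts = [np.atleast_1d(beta), np.atleast_1d(gamma)]
    if log_theta is not None:
        parts.append([log_theta])
    return np.concatenate(parts)


class TestLoglik:
    def test_single_zero_observation_closed_form(self):
        # pi = 0.5 (gamma=0), lam = 1 (beta=0): log(0.5 + 0.5 e^-1)
        ll = zi_loglik(_pack([0.0], [0.0]), [0], np.ones((1, 1)),
                       np.ones((1, 1)))
        assert ll == pytest.approx(np.log(0.5 + 0.5 * np.exp(-1)), abs=1e-10)
        assert ll == pytest.approx(-0.37989, abs=1e-5)

    def test_mixture_collapses_to_poisson_when_pi_zero(self, rng):
        y = rng.poisson(2.0, 50)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        Z = np.ones((50, 1))
        beta = np.array([0.7, 0.2])
        ll = zi_loglik(_pack(beta, [-40.0]), y, X, Z)
        oracle = stats.poisson.logpmf(y, np.exp(X @ beta)).sum()
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_pi_zero_negbin_equals_independent_pmf(self, rng):
        y = rng.poisson(3.0, 40)
        X = np.ones((40, 1))
        Z = np.ones((40, 1))
        theta, lam = 4.0, np.exp(1.1)
        ll = zi_loglik(_pack([1.1], [-40.0], np.log(theta)), y, X, Z,
                       family="negbin")
        oracle = stats.nbinom.logpmf(y, theta, theta / (theta + lam)).sum()
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_zinb_with_large_theta_equals_zip(self):
        y = np.array([0, 1, 2, 3, 0])
        X = Z = np.ones((5, 1))
        ll_zip = zi_loglik(_pack([0.6], [-0.4]), y, X, Z)
        ll_zinb = zi_loglik(_pack([0.6], [-0.4], np.log(1e7)), y, X, Z,
                            family="negbin")
        assert ll_zinb == pytest.approx(ll_zip, abs=1e-6)

    def test_weights_multiply_contributions(self, rng):
        y = rng.poisson(1.5, 25)
        X = Z = np.ones((25, 1))
        p = _pack([0.3], [-0.5])
        w = rng.integers(1, 4, 25).astype(float)
        ll_w = zi_loglik(p, y, X, Z, weights=w)
        per_obs = np.array([zi_loglik(p, [yi], np.ones((1, 1)),
                                      np.ones((1, 1))) for yi in y])
        assert ll_w == pytest.approx(np.sum(w * per_obs), abs=1e-8)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            zi_loglik(_pack([0.0], [0.0]), [1.5], np.ones((1, 1)),
                      np.ones((1, 1)))

    def test_analytic_gradient_matches_finite_differences(self, rng):
        from gradientzi.zicount import _ll_terms
        y = rng.poisson(2.0, 60).astype(float)
        y[rng.random(60) < 0.3] = 0
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        Z = np.column_stack([np.ones(60), rng.normal(size=60)])
        w = rng.uniform(0.5, 2.0, 60)
        for family, p in (("poisson", _pack([0.4, 0.2], [-0.3, 0.5])),
                          ("negbin", _pack([0.4, 0.2], [-0.3, 0.5], 0.7))):
            _, g = _ll_terms(p, y, X, Z, family, w, "frequency")
            num = np.array([
                (_ll_terms(p + e, y, X, Z, family, w, "frequency",
                           want_grad=False)[0]
                 - _ll_terms(p - e, y, X, Z, family, w, "frequency",
                             want_grad=False)[0]) / 2e-6
                for e in np.eye(len(p)) * 1e-6])
            np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-5)


class TestFit:
    def test_zip_parameter_recovery_within_3se(self, zip_dataset):
        df, truth = zip_dataset
        fit = fit_zicount(df, "y", ["x"], ["z"])
        assert fit.converged
        for part, terms, true_vals in (("count", ["Intercept", "x"],
                                        truth["beta"]),
                                       ("zero", ["Intercept", "z"],
                                        truth["gamma"])):
            for term, tv in zip(terms, true_vals):
                row = fit.summary[(fit.summary.part == part)
                                  & (fit.summary.term == term)]
                est, se = row.estimate.iloc[0], row.se.iloc[0]
                assert abs(est - tv) < 3 * se, (part, term, est, tv, se)

    def test_poisson_mle_limit_on_all_positive_counts(self, rng):
        y = rng.poisson(8.0, 800) + 1  # strictly positive
        df = pd.DataFrame({"y": y})
        fit = fit_zicount(df, "y", [], [])
        pi_hat = fit.model.structural_zero_prob(np.empty((1, 0)))[0]
        assert pi_hat < 0.01
        # with pi ~ 0, the count intercept is the plain Poisson MLE log(ybar)
        assert fit.coef("count", "Intercept") == pytest.approx(
            np.log(y.mean()), abs=5e-3)

    def test_refit_is_deterministic(self, zip_dataset):
        df, _ = zip_dataset
        f1 = fit_zicount(df, "y", ["x"], ["z"])
        f2 = fit_zicount(df, "y", ["x"], ["z"])
        pd.testing.assert_frame_equal(f1.summary, f2.summary)
        assert f1.aic == f2.aic

    def test_aic_identity(self, zip_dataset):
        df, _ = zip_dataset
        for family in ("poisson", "negbin"):
            fit = fit_zicount(df, "y", ["x"], ["z"], family=family)
            k = 4 + (1 if family == "negbin" else 0)
            assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, abs=1e-9)

    def test_doubling_weights_doubles_loglik_not_estimates(self, zip_dataset):
        df, _ = zip_dataset
        w1 = np.ones(len(df))
        f1 = fit_zicount(df, "y", ["x"], ["z"], weights=w1)
        f2 = fit_zicount(df, "y", ["x"], ["z"], weights=2 * w1)
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-6)
        np.testing.assert_allclose(f2.summary.estimate, f1.summary.estimate,
                                   atol=1e-5)

    def test_matches_statsmodels_zip_reference(self, zip_dataset):
        """Independent cross-check against statsmodels' ZIP MLE."""
        import statsmodels.api as sm
        from statsmodels.discrete.count_model import ZeroInflatedPoisson
        df, _ = zip_dataset
        mine = fit_zicount(df, "y", ["x"], ["z"])
        ref = ZeroInflatedPoisson(
            df["y"], sm.add_constant(df[["x"]]),
            exog_infl=sm.add_constant(df[["z"]])).fit(disp=0)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-5)
        # statsmodels orders [infl..., count...]
        np.testing.assert_allclose(
            mine.summary.estimate.to_numpy(),
            np.r_[ref.params.iloc[2:], ref.params.iloc[:2]], atol=2e-4)

    def test_rank_deficiency_error_names_columns(self, zip_dataset):
        df, _ = zip_dataset
        df = df.assign(x2=df["x"])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_zicount(df, "y", ["x", "x2"], ["z"])

    def test_all_zero_counts_rejected(self):
        df = pd.DataFrame({"y": np.zeros(20, dtype=int),
                           "x": np.arange(20.0)})
        with pytest.raises(ValueError, match="positive count"):
            fit_zicount(df, "y", ["x"], [])

    def test_offset_weights_mode_scales_mean(self, rng):
        n = 1500
        expo = rng.integers(1, 6, n).astype(float)
        lam = 1.8 * expo
        y = rng.poisson(lam)
        y[rng.random(n) < 0.2] = 0
        df = pd.DataFrame({"y": y})
        fit = fit_zicount(df, "y", [], [], weights=expo,
                          weights_mode="offset")
        assert fit.coef("count", "Intercept") == pytest.approx(np.log(1.8),
                                                               abs=0.1)


class TestAbundanceChange:
    def test_examples(self):
        assert abundance_change(0.027) == pytest.approx(1.027, abs=1e-3)
        assert abundance_change(0.0) == 1.0
        assert abundance_change(-2.435) == pytest.approx(0.0876, abs=1e-4)
        assert percent_change(-2.435) == pytest.approx(-91.24, abs=0.01)


class TestStructuralZeroProb:
    def test_logistic_of_urban_distance(self):
        # zero-part intercept -1.583, slope 0.033 per metre
        assert structural_zero_prob([-1.583, 0.033], [0.0]) == pytest.approx(
            0.1704, abs=1e-4)

    def test_all_zero_coefs_give_half(self):
        assert structural_zero_prob([0.0, 0.0], [123.0]) == 0.5

    def test_positive_slope_limit_is_one(self):
        assert structural_zero_prob([-1.583, 0.033],
                                    [1e6]) == pytest.approx(1.0)

    def test_monotone_in_covariate_per_sign(self):
        d = np.linspace(0, 300, 50).reshape(-1, 1)
        p = structural_zero_prob([-1.583, 0.033], d)
        assert np.all(np.diff(p) > 0)

    def test_name_count_mismatch(self):
        with pytest.raises(ValueError, match="covariate"):
            structural_zero_prob([-1.0, 0.5, 0.2], np.ones((3, 1)))


class TestBackwardElimination:
    def _sim(self, seed, n=600):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)   # null covariate: true coefficient 0
        lam = np.exp(0.8 + 0.6 * x1)
        y = rng.poisson(lam)
        y[rng.random(n) < 0.25] = 0
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2})

    def test_null_covariate_usually_eliminated(self):
        dropped = 0
        for seed in range(12):
            trace = backward_eliminate(self._sim(seed), "y", ["x1", "x2"], [])
            if "x2" not in trace.final.count_terms:
                dropped += 1
        assert dropped >= 8  # most seeded replicates

    def test_minimal_model_gives_trace_of_length_one(self):
        df = self._sim(3)
        trace = backward_eliminate(df, "y", ["x1"], [])
        # x1 truly matters, so no drop is accepted
        assert len(trace.steps) == 1
        assert trace.final.count_terms == ["x1"]

    def test_aic_nonincreasing_along_accepted_steps(self):
        trace = backward_eliminate(self._sim(1), "y", ["x1", "x2"], [])
        aics = trace.aic_path
        assert all(b <= a + 1e-8 for a, b in zip(aics, aics[1:]))

    def test_exact_tie_drops_later_listed_term(self):
        # response invariant under a half rotation, xb = rotated xa: the
        # models after dropping xa or xb are row permutations of each
        # other, so their AICs tie exactly
        y = np.tile([0, 1, 2, 0, 0, 1, 2, 0], 8)
        xa = np.tile([2.0, 1, 1, 0, 0, 0, 0, 0], 8)
        xb = np.tile(np.roll([2.0, 1, 1, 0, 0, 0, 0, 0], 4), 8)
        df = pd.DataFrame({"y": y, "xa": xa, "xb": xb})
        trace = backward_eliminate(df, "y", ["xa", "xb"], [])
        assert len(trace.steps) > 1
        assert trace.steps["dropped"].iloc[1] == "count:xb"


class TestZeroPartLR:
    def test_strong_zero_covariate_has_large_chi2(self, zip_dataset):
        df, _ = zip_dataset
        fit = fit_zicount(df, "y", ["x"], ["z"])
        lr = zero_part_lr_tests(df, fit)
        row = lr[lr.term == "z"].iloc[0]
        assert row["chi2"] > 3.84 and row["p"] < 0.05
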