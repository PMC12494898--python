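"""Asymmetric-Laplace front regression: density, joint posterior, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

from paleodispersal.data_prep import BIR_KISEIBA
from paleodispersal.inference import McmcConfig
from paleodispersal.quantile_dispersal import (QuantileModelSpec,
                                               QuantilePriors,
                                               asymlaplace_logpdf,
                                               asymlaplace_rvs,
                                               fit_quantile_model,
                                               point_calibrate,
                                               quantile_joint_logpost,
                                               slope_summary)


class TestAsymLaplaceDensity:
    def test_value_at_the_location(self):
        assert asymlaplace_logpdf(0.0, 0.0, 1.0, 0.5) == pytest.approx(np.log(0.25))

    @pytest.mark.parametrize("mu,lam,tau", [(0.0, 1.0, 0.5), (2.0, 0.7, 0.05),
                                            (-1.0, 3.0, 0.95)])
    def test_density_integrates_to_one(self, mu, lam, tau):
        pdf = lambda x: np.exp(asymlaplace_logpdf(x, mu, lam, tau))
        lower, _ = integrate.quad(pdf, -np.inf, mu, limit=200)
        upper, _ = integrate.quad(pdf, mu, np.inf, limit=200)
        assert lower + upper == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_at_half(self):
        for x in (0.3, 1.7, -2.2):
            assert asymlaplace_logpdf(x, 0.5, 1.3, 0.5) == pytest.approx(
                asymlaplace_logpdf(1.0 - x, 0.5, 1.3, 0.5))

    def test_location_is_the_tau_quantile_of_draws(self, rng):
        draws = asymlaplace_rvs(10.0, 2.0, 0.2, size=40000, rng=rng)
        assert np.quantile(draws, 0.2) == pytest.approx(10.0, abs=0.15)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            asymlaplace_logpdf(0.0, 0.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            asymlaplace_logpdf(0.0, 0.0, 1.0, 1.5)


class TestJointLogPosterior:
    def spec(self):
        return QuantileModelSpec(
            origin=BIR_KISEIBA, tau=0.05,
            priors=QuantilePriors(gamma0_mean=9000.0))

    def test_zero_samples_returns_prior_only(self, identity_curve):
        spec = self.spec()
        lp = quantile_joint_logpost(np.array([9000.0, 0.0, np.log(300.0)]),
                                    np.array([]), np.array([]), np.array([]),
                                    identity_curve, spec)
        # independent prior arithmetic
        expected = (0.0
                    - 0.5 * (0.0 / spec.priors.gamma1_sd) ** 2
                    - 300.0 / spec.priors.lambda_mean + np.log(300.0))
        assert lp == pytest.approx(expected)

    def test_single_sample_matches_grid_oracle(self, identity_curve):
        spec = self.spec()
        d = np.array([500.0])
        x = np.array([9100.0])
        err = np.array([60.0])
        tau_eff = spec.effective_tau
        for theta in (8700.0, 9000.0, 9400.0):
            for gamma0 in (8800.0, 9200.0):
                params = np.array([gamma0, -0.3, np.log(200.0), theta])
                # independent scalar recomputation
                mu = gamma0 + -0.3 * 500.0
                u = (theta - mu) / 200.0
                al = (np.log(tau_eff * (1 - tau_eff) / 200.0)
                      - u * (tau_eff - (u < 0)))
                cal = -0.5 * np.log(2 * np.pi) - np.log(60.0) \
                    - 0.5 * ((x[0] - theta) / 60.0) ** 2
                prior = (-0.5 * ((gamma0 - 9000.0) / 2000.0) ** 2
                         - 0.5 * (-0.3 / spec.priors.gamma1_sd) ** 2
                         - 200.0 / spec.priors.lambda_mean + np.log(200.0))
                expected = al + cal + prior
                assert quantile_joint_logpost(params, d, x, err,
                                              identity_curve, spec) == \
                    pytest.approx(expected)

    def test_duplicate_sample_doubles_the_likelihood(self, identity_curve):
        spec = self.spec()
        base = np.array([9000.0, -0.2, np.log(250.0)])
        one = quantile_joint_logpost(np.append(base, 9050.0),
                                     np.array([100.0]), np.array([9060.0]),
                                     np.array([50.0]), identity_curve, spec)
        two = quantile_joint_logpost(np.append(base, [9050.0, 9050.0]),
                                     np.array([100.0, 100.0]),
                                     np.array([9060.0, 9060.0]),
                                     np.array([50.0, 50.0]), identity_curve, spec)
        prior = quantile_joint_logpost(base, np.array([]), np.array([]),
                                       np.array([]), identity_curve, spec)
        assert two - prior == pytest.approx(2 * (one - prior))

    def test_off_support_latent_age_is_rejected_state(self, identity_curve):
        lp = quantile_joint_logpost(np.array([9000.0, 0.0, np.log(300.0), 500.0]),
                                    np.array([100.0]), np.array([9000.0]),
                                    np.array([50.0]), identity_curve, self.spec())
        assert lp == -np.inf


def _toy_data(rng, n=40, slope=-0.4, lam=80.0, curve_support=(7000, 12000)):
    d = rng.uniform(0, 2000, n)
    theta = asymlaplace_rvs(10200.0 + slope * d, lam, 0.95, size=n, rng=rng)
    theta = np.clip(theta, curve_support[0] + 200, curve_support[1] - 200)
    err = np.full(n, 40.0)
    x = theta + err * rng.standard_normal(n)
    return pd.DataFrame({"c14_age": x, "c14_error": err,
                         "dist_bir_kiseiba": d, "ceramic": True})


class TestFitQuantileModel:
    CFG = McmcConfig(n_chains=2, n_iterations=1200, n_keep=300, seed=5)

    def test_same_seed_reproduces_draws(self, identity_curve, rng):
        data = _toy_data(rng)
        spec = QuantileModelSpec(origin=BIR_KISEIBA)
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            a = fit_quantile_model(spec, data, identity_curve, self.CFG)
            b = fit_quantile_model(spec, data, identity_curve, self.CFG)
        assert np.array_equal(a.gamma1, b.gamma1)
        assert np.array_equal(a.lam, b.lam)

    def test_empty_data_rejected(self, identity_curve):
        spec = QuantileModelSpec(origin=BIR_KISEIBA)
        with pytest.raises(ValueError):
            fit_quantile_model(spec, _toy_data(np.random.default_rng(0)).iloc[:0],
                               identity_curve, self.CFG)

    def test_missing_distance_column_rejected(self, identity_curve, rng):
        data = _toy_data(rng).drop(columns=["dist_bir_kiseiba"])
        with pytest.raises(ValueError, match="dist_"):
            fit_quantile_model(QuantileModelSpec(origin=BIR_KISEIBA), data,
                               identity_curve, self.CFG)

    def test_strong_slope_recovered_within_two_sd(self, identity_curve):
        rng = np.random.default_rng(77)
        data = _toy_data(rng, n=120, slope=-0.5)
        cfg = McmcConfig(n_chains=2, n_iterations=4000, n_keep=1000, seed=6)
        post = fit_quantile_model(QuantileModelSpec(origin=BIR_KISEIBA), data,
                                  identity_curve, cfg)
        s = slope_summary(post)
        assert abs(s["mean"] - (-0.5)) < 2 * s["sd"]

    def test_flat_curve_limit_matches_check_loss_minimiser(self, identity_curve):
        # with tiny measurement error the latent ages pin to the data and
        # the fit collapses to plain check-loss quantile regression
        rng = np.random.default_rng(42)
        n = 150
        d = rng.uniform(0, 2000, n)
        theta = asymlaplace_rvs(10000.0 - 0.45 * d, 70.0, 0.95, size=n, rng=rng)
        data = pd.DataFrame({"c14_age": theta, "c14_error": np.full(n, 1.0),
                             "dist_bir_kiseiba": d})

        def check_loss(b):
            u = theta - (b[0] + b[1] * d)
            return np.sum(u * (0.95 - (u < 0)))

        direct = optimize.minimize(check_loss, [10000.0, 0.0],
                                   method="Nelder-Mead").x
        cfg = McmcConfig(n_chains=2, n_iterations=5000, n_keep=1000, seed=8)
        post = fit_quantile_model(QuantileModelSpec(origin=BIR_KISEIBA), data,
                                  identity_curve, cfg)
        s = slope_summary(post)
        assert s["mean"] == pytest.approx(direct[1], abs=max(3 * s["sd"], 0.02))


class TestSlopeSummary:
    def make_posterior(self, draws):
        post = object.__new__(
            __import__("paleodispersal.quantile_dispersal",
                       fromlist=["QuantilePosterior"]).QuantilePosterior)
        post.gamma1 = np.asarray(draws, dtype=float).reshape(1, -1)
        return post

    def test_all_positive_draws_exclude_zero(self):
        s = slope_summary(self.make_posterior(np.linspace(0.1, 0.5, 100)))
        assert not s["includes_zero"] and s["prob_negative"] == 0.0

    def test_symmetric_draws_include_zero(self):
        s = slope_summary(self.make_posterior(np.linspace(-1, 1, 101)))
        assert s["includes_zero"] and s["prob_negative"] == pytest.approx(0.5, abs=0.01)

    def test_interval_endpoints_are_empirical_quantiles(self, rng):
        draws = rng.standard_normal(500)
        s = slope_summary(self.make_posterior(draws), level=0.8)
        assert s["lower"] == pytest.approx(np.quantile(draws, 0.1))
        assert s["upper"] == pytest.approx(np.quantile(draws, 0.9))


def test_point_calibrate_inverts_monotone_curves(wiggle_curve):
    theta = np.array([8000.0, 9500.0, 11000.0])
    mu = np.interp(theta, wiggle_curve.cal_age, wiggle_curve.c14_age)
    assert np.allclose(point_calibrate(mu, wiggle_curve), theta, atol=1e-6)
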