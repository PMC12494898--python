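"""Multi-origin binomial diffusion model: scaling, likelihood, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from paleodispersal.data_prep import (BIR_KISEIBA, OUNJOUGOU, PreparedDataset,
                                      attach_distances)
from paleodispersal.inference import McmcConfig
from paleodispersal.origin_diffusion import (DiffusionModelSpec,
                                             DiffusionPosterior,
                                             ScalingConstants,
                                             diffusion_joint_logpost,
                                             diffusion_logit,
                                             fit_diffusion_model, make_spec,
                                             multi_origin_probability,
                                             posterior_mean_surface,
                                             scale_covariates, zscore)
from paleodispersal.synthetic_data import SyntheticConfig, gen_full_study


class TestScaling:
    def test_scaled_covariates_are_standardised(self, rng):
        theta = rng.uniform(7000, 12000, 50)
        d = rng.uniform(0, 3000, (50, 2))
        t_s, d_s, _ = scale_covariates(theta, d)
        assert t_s.mean() == pytest.approx(0.0, abs=1e-12)
        assert t_s.std() == pytest.approx(1.0)
        assert np.allclose(d_s.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(d_s.std(axis=0), 1.0)

    def test_round_trip_recovers_inputs(self, rng):
        theta = rng.uniform(7000, 12000, 30)
        d = rng.uniform(0, 3000, (30, 1))
        t_s, d_s, c = scale_covariates(theta, d)
        assert np.allclose(t_s * c.theta_sd + c.theta_mean, theta, rtol=1e-12)
        assert np.allclose(d_s[:, 0] * c.d_sd[0] + c.d_mean[0], d[:, 0],
                           rtol=1e-12, atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            zscore(np.full(5, 3.0))


class TestDiffusionLogit:
    def test_all_zero_coefficients_give_half(self):
        assert diffusion_logit((0, 0, 0, 0), 0.7, -1.2) == pytest.approx(0.5)

    def test_probability_decreases_with_distance(self):
        block = (0.0, 0.0, 1.0, 0.0)
        assert diffusion_logit(block, 0.0, 0.0) > diffusion_logit(block, 0.0, 2.0)

    def test_probability_increases_toward_the_present(self):
        # larger theta = older; positive b_time lowers the odds back in time
        block = (0.0, 1.0, 0.0, 0.0)
        assert diffusion_logit(block, -1.0, 0.0) > diffusion_logit(block, 1.0, 0.0)

    def test_linear_predictor_arithmetic(self):
        got = diffusion_logit((1.0, 0.5, 0.5, 0.2), 1.0, 1.0)
        assert got == pytest.approx(expit(1.0 - 0.5 - 0.5 + 0.2))


class TestMultiOriginProbability:
    def test_takes_the_maximum(self):
        blocks = np.array([[10.0, 0, 0, 0], [-10.0, 0, 0, 0]])
        p = multi_origin_probability(blocks, 0.0, np.array([0.0, 0.0]))
        assert p == pytest.approx(expit(10.0))

    def test_single_origin_reduces_to_logit(self, rng):
        block = rng.standard_normal(4)
        t, d = 0.4, -0.8
        assert multi_origin_probability(block[None, :], t, np.array([d])) == \
            pytest.approx(diffusion_logit(block, t, d))

    def test_dominates_every_component(self, rng):
        blocks = rng.standard_normal((3, 4))
        t = rng.standard_normal(10)
        d = rng.standard_normal((10, 3))
        p = multi_origin_probability(blocks, t, d)
        for k in range(3):
            assert np.all(p >= diffusion_logit(blocks[k], t, d[:, k]) - 1e-12)

    def test_adding_an_origin_never_decreases_p(self, rng):
        blocks = rng.standard_normal((3, 4))
        t = rng.standard_normal(20)
        d = rng.standard_normal((20, 3))
        p2 = multi_origin_probability(blocks[:2], t, d[:, :2])
        p3 = multi_origin_probability(blocks, t, d)
        assert np.all(p3 >= p2 - 1e-12)

    def test_block_distance_mismatch_rejected(self):
        with pytest.raises(ValueError, match="block"):
            multi_origin_probability(np.zeros((2, 4)), 0.0, np.zeros(3))


def _tiny_prepared(rng, n=30, origins=(BIR_KISEIBA, OUNJOUGOU)):
    df = pd.DataFrame({
        "lab_id": [f"L{i}" for i in range(n)],
        "site_id": [f"S{i}" for i in range(n)],
        "lon": rng.uniform(-10, 35, n), "lat": rng.uniform(11, 33, n),
        "c14_age": rng.uniform(7500, 11500, n),
        "c14_error": rng.uniform(40, 100, n),
        "ceramic": rng.random(n) < 0.5,
    })
    return attach_distances(df, list(origins))


class TestJointLogPosterior:
    def test_zero_blocks_give_bernoulli_half(self, identity_curve, rng):
        prep = _tiny_prepared(rng)
        spec = make_spec(prep, identity_curve)
        n = len(prep.samples)
        theta = prep.samples["c14_age"].to_numpy()
        params = np.concatenate([np.zeros(8), theta])
        lp = diffusion_joint_logpost(params, prep, identity_curve, spec)
        # subtract the calibration and (zero) prior parts -> n log(1/2)
        from paleodispersal.calibration import c14_loglik
        cal = np.sum(c14_loglik(prep.samples["c14_age"].to_numpy(),
                                prep.samples["c14_error"].to_numpy(),
                                theta, identity_curve))
        assert lp - cal == pytest.approx(n * np.log(0.5))

    def test_single_sample_matches_scalar_oracle(self, identity_curve, rng):
        prep = _tiny_prepared(rng, n=1, origins=(BIR_KISEIBA,))
        row = prep.samples.iloc[0]
        scaling = ScalingConstants(9000.0, 1000.0, (2000.0,), (800.0,))
        spec = DiffusionModelSpec((BIR_KISEIBA,), scaling, prior_sd=10.0)
        block = np.array([0.8, 1.1, -0.4, 0.25])
        theta = 9300.0
        params = np.concatenate([block, [theta]])
        t_s = (theta - 9000.0) / 1000.0
        d_s = (row["dist_bir_kiseiba"] - 2000.0) / 800.0
        eta = block[0] - block[1] * t_s - block[2] * d_s + block[3] * d_s * t_s
        p = expit(eta)
        bern = np.log(p) if row["ceramic"] else np.log(1 - p)
        sigma = row["c14_error"]
        cal = (-0.5 * np.log(2 * np.pi) - np.log(sigma)
               - 0.5 * ((row["c14_age"] - theta) / sigma) ** 2)
        prior = -0.5 * np.sum((block / 10.0) ** 2)
        assert diffusion_joint_logpost(params, prep, identity_curve, spec) == \
            pytest.approx(bern + cal + prior)

    def test_invariant_to_sample_order(self, identity_curve, rng):
        prep = _tiny_prepared(rng, n=12)
        spec = make_spec(prep, identity_curve)
        theta = prep.samples["c14_age"].to_numpy()
        blocks = rng.standard_normal(8)
        lp = diffusion_joint_logpost(np.concatenate([blocks, theta]),
                                     prep, identity_curve, spec)
        perm = rng.permutation(12)
        shuffled = PreparedDataset(
            prep.samples.iloc[perm].reset_index(drop=True), prep.origins)
        lp2 = diffusion_joint_logpost(np.concatenate([blocks, theta[perm]]),
                                      shuffled, identity_curve, spec)
        assert lp == pytest.approx(lp2)

    def test_off_support_theta_is_rejected_state(self, identity_curve, rng):
        prep = _tiny_prepared(rng, n=1)
        scaling = ScalingConstants(9000.0, 1000.0, (1500.0, 1500.0),
                                   (700.0, 700.0))
        spec = DiffusionModelSpec(prep.origins, scaling)
        params = np.concatenate([np.zeros(8), [100.0]])
        assert diffusion_joint_logpost(params, prep, identity_curve, spec) == -np.inf


class TestFitDiffusionModel:
    CFG = McmcConfig(n_chains=2, n_iterations=1000, n_keep=200, seed=11)

    @pytest.fixture(scope="class")
    def study(self):
        cfg = SyntheticConfig(
            seed=5, n_sites=40, origins=(BIR_KISEIBA, OUNJOUGOU),
            true_blocks={"bir_kiseiba": (-1.0, 1.2, 2.0, 0.3),
                         "ounjougou": (-0.8, 1.5, 2.2, 0.0)})
        df, _ = gen_full_study(cfg)
        return PreparedDataset(df, cfg.origins), cfg.make_curve()

    def test_same_seed_reproduces_draws(self, study):
        prep, curve = study
        spec = make_spec(prep, curve)
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            a = fit_diffusion_model(spec, prep, curve, self.CFG)
            b = fit_diffusion_model(spec, prep, curve, self.CFG)
        assert np.array_equal(a.blocks, b.blocks)
        assert np.array_equal(a.pointwise_loglik, b.pointwise_loglik)

    def test_loglik_matrix_consistent_with_joint_posterior(self, study):
        prep, curve = study
        spec = make_spec(prep, curve)
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            post = fit_diffusion_model(spec, prep, curve, self.CFG,
                                       store_theta=True)
        from paleodispersal.calibration import c14_loglik
        y = prep.samples["ceramic"].to_numpy(dtype=float)
        x = prep.samples["c14_age"].to_numpy()
        err = prep.samples["c14_error"].to_numpy()
        flat_blocks = post.stacked_blocks()
        for s in (0, len(flat_blocks) // 2, len(flat_blocks) - 1):
            params = np.concatenate([flat_blocks[s].ravel(),
                                     post.theta_draws[s]])
            joint = diffusion_joint_logpost(params, prep, curve, spec)
            cal = np.sum(c14_loglik(x, err, post.theta_draws[s], curve))
            prior = -0.5 * np.sum((flat_blocks[s] / spec.prior_sd) ** 2)
            assert post.pointwise_loglik[s].sum() == pytest.approx(
                joint - cal - prior, abs=1e-8)

    def test_all_presence_data_warns_of_separation(self, study, rng):
        prep, curve = study
        df = prep.samples.copy()
        df["ceramic"] = True
        all_present = PreparedDataset(df, prep.origins)
        spec = make_spec(all_present, curve)
        with pytest.warns(UserWarning, match="separation"):
            fit_diffusion_model(spec, all_present, curve,
                                McmcConfig(n_chains=2, n_iterations=200,
                                           n_keep=50, seed=1))

    def test_posterior_probabilities_lie_in_unit_interval(self, study):
        prep, curve = study
        spec = make_spec(prep, curve)
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            post = fit_diffusion_model(spec, prep, curve, self.CFG)
        assert np.all((post.p_mean >= 0) & (post.p_mean <= 1))


class TestPosteriorSurface:
    def toy_posterior(self):
        scaling = ScalingConstants(9000.0, 1000.0, (1500.0, 1500.0),
                                   (700.0, 700.0))
        spec = DiffusionModelSpec((BIR_KISEIBA, OUNJOUGOU), scaling)
        blocks = np.array([
            [[2.0, 0.5, 1.0, 0.0], [0.5, 0.2, 0.8, 0.1]],
            [[1.0, 0.3, 1.2, 0.2], [1.5, 0.4, 0.6, 0.0]],
        ])  # 2 draws
        post = object.__new__(DiffusionPosterior)
        post.blocks = blocks[None, :, :, :]  # 1 chain
        post.spec = spec
        return post

    def test_two_draw_surface_equals_hand_average(self):
        post = self.toy_posterior()
        lons = np.array([0.0, 15.0, 30.0])
        lats = np.array([15.0, 25.0])
        surf = posterior_mean_surface(post, lons, lats, 9000.0)
        from paleodispersal.data_prep import great_circle_km
        for i, lat in enumerate(lats):
            for j, lon in enumerate(lons):
                d = np.array([great_circle_km(lon, lat, o.lon, o.lat)
                              for o in post.spec.origins])
                d_s = post.spec.scaling.scale_d(d)
                t_s = post.spec.scaling.scale_theta(9000.0)
                draws = post.blocks[0]
                expected = np.mean([
                    multi_origin_probability(draws[s], t_s, d_s)
                    for s in range(2)])
                assert surf.prob[i, j] == pytest.approx(expected)

    def test_probabilities_in_unit_interval(self):
        surf = posterior_mean_surface(self.toy_posterior(),
                                      np.linspace(-15, 35, 8),
                                      np.linspace(11, 33, 6), 8500.0)
        assert np.all((surf.prob >= 0) & (surf.prob <= 1))

    def test_pure_distance_decay_is_monotone(self):
        # b_time = b_interaction = 0 collapses to distance-decay logistic
        scaling = ScalingConstants(9000.0, 1000.0, (1500.0,), (700.0,))
        spec = DiffusionModelSpec((BIR_KISEIBA,), scaling)
        block = np.array([[0.5, 0.0, 1.3, 0.0]])
        d_s = np.linspace(-2, 2, 50)
        p = [multi_origin_probability(block, 0.0, np.array([d])) for d in d_s]
        assert np.all(np.diff(p) < 0)


def test_make_spec_restricts_to_requested_origins(identity_curve, rng):
    prep = _tiny_prepared(rng)
    spec = make_spec(prep, identity_curve, origins=(OUNJOUGOU,))
    assert spec.n_origins == 1
    assert spec.origins[0].name == "ounjougou"
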