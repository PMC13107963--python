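"""Schedule algebra, forward/posterior identities, NLL oracle, sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbdiff.conditioning import (ConditionConfig, ConditionEncoder,
                                      Denoiser, DenoiserOutput)
from perturbdiff.diffusion import (DiffusionTrainConfig, NoiseSchedule,
                                   ScheduleError, build_schedule, forward_marginal,
                                   forward_step, interpolate_variance, kl_loss,
                                   nll_loss, posterior_target, sample,
                                   train_diffusion)


class TestSchedule:
    @settings(derandomize=True, max_examples=40)
    @given(T=st.integers(2, 400),
           beta_min=st.floats(1e-6, 1e-3),
           spread=st.floats(1.5, 50.0))
    def test_invariants_for_any_valid_schedule(self, T, beta_min, spread):
        beta_max = min(beta_min * spread, 0.5)
        s = build_schedule(T, beta_min, beta_max)
        assert s.beta[0] == pytest.approx(beta_min)
        assert s.beta[-1] == pytest.approx(beta_max)
        assert np.all(np.diff(s.beta) > 0)
        assert np.all((s.beta > 0) & (s.beta < 1))
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert np.all((s.alpha_bar > 0) & (s.alpha_bar < 1))
        assert s.beta_tilde[0] == 0.0
        assert np.all(s.beta_tilde <= s.beta + 1e-18)

    def test_linear_midpoint_at_default_endpoints(self):
        s = build_schedule(101)
        assert s.beta[50] == pytest.approx((1e-5 + 0.01) / 2)
        assert s.beta[50] == pytest.approx(0.005005)

    def test_constant_beta_degenerate_geometric_product(self):
        s = build_schedule(10, 0.01, 0.01, allow_constant=True)
        t = np.arange(1, 11)
        np.testing.assert_allclose(s.alpha_bar, (1 - 0.01) ** t, rtol=1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(T=1), dict(T=10, beta_min=0.0), dict(T=10, beta_max=1.0),
        dict(T=10, beta_min=0.02, beta_max=0.01)])
    def test_invalid_configurations_raise(self, kwargs):
        with pytest.raises(ScheduleError):
            build_schedule(**kwargs)


class TestForwardProcess:
    def test_marginal_from_zero_signal_has_schedule_variance(self, rng):
        s = build_schedule(50)
        noise = rng.standard_normal((200_000, 1))
        z = forward_marginal(np.zeros((200_000, 1)), 30, s, noise)
        expected = 1.0 - s.alpha_bar[29]
        se = expected * np.sqrt(2.0 / (len(z) - 1))
        assert abs(z.var() - expected) < 3 * se

    def test_step_with_zero_noise_is_pure_shrinkage(self, rng):
        s = build_schedule(20)
        z = rng.standard_normal((3, 4))
        out = forward_step(z, 5, s, np.zeros_like(z))
        np.testing.assert_allclose(out, np.sqrt(1 - s.beta[4]) * z, rtol=1e-14)

    def test_two_step_variance_accumulation(self, rng):
        # z0-anchored: Var(z_t) after two transitions = 1 - alpha_t alpha_{t-1}
        s = build_schedule(10, 0.05, 0.2)
        n = 400_000
        z0 = np.zeros((n, 1))
        z1 = forward_step(z0, 1, s, rng.standard_normal((n, 1)))
        z2 = forward_step(z1, 2, s, rng.standard_normal((n, 1)))
        expected = 1 - s.alpha[0] * s.alpha[1]
        se = expected * np.sqrt(2.0 / (n - 1))
        assert abs(z2.var() - expected) < 3 * se

    def test_iterated_steps_match_closed_form_moments(self, rng):
        s = build_schedule(30)
        n, d, t_check = 50_000, 4, 12
        z0 = np.tile(rng.normal(size=(1, d)), (n, 1))
        z = z0.copy()
        for t in range(1, t_check + 1):
            z = forward_step(z, t, s, rng.standard_normal((n, d)))
        mean_expected = np.sqrt(s.alpha_bar[t_check - 1]) * z0[0]
        var_expected = 1 - s.alpha_bar[t_check - 1]
        se_mean = np.sqrt(var_expected / n)
        assert np.all(np.abs(z.mean(axis=0) - mean_expected) < 3 * se_mean)
        se_var = var_expected * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(z.var(axis=0) - var_expected) < 3 * se_var)

    def test_timestep_bounds_enforced(self, rng):
        s = build_schedule(10)
        z = rng.standard_normal((2, 3))
        with pytest.raises(ScheduleError):
            forward_marginal(z, 11, s, z)
        with pytest.raises(ScheduleError):
            forward_step(z, 0, s, z)


class TestPosterior:
    def test_t1_returns_z0(self, rng):
        s = build_schedule(100)
        z0 = rng.standard_normal((5, 8))
        z1 = rng.standard_normal((5, 8))
        out = posterior_target(z0, z1, 1, s, rng.standard_normal((5, 8)))
        # beta_tilde_1 = 0 kills the noise; coefficient arithmetic only
        np.testing.assert_allclose(out, z0, atol=1e-9)

    def test_zero_noise_interpolates_deterministically(self, rng):
        s = build_schedule(50)
        z0 = rng.standard_normal((1, 4))
        t = 20
        z_t = forward_marginal(z0, t, s, np.zeros_like(z0))
        out = posterior_target(z0, z_t, t, s, np.zeros_like(z0))
        beta = s.beta[t - 1]
        ab, ab_prev = s.alpha_bar[t - 1], s.alpha_bar[t - 2]
        expected = (np.sqrt(ab_prev) * beta / (1 - ab) * z0
                    + np.sqrt(1 - beta) * (1 - ab_prev) / (1 - ab) * z_t)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_monte_carlo_moments_match_coefficients(self, rng):
        s = build_schedule(40)
        t, n = 15, 100_000
        z0 = rng.standard_normal(3)
        z_t = rng.standard_normal(3)
        draws = posterior_target(np.tile(z0, (n, 1)), np.tile(z_t, (n, 1)),
                                 t, s, rng.standard_normal((n, 3)))
        beta = s.beta[t - 1]
        ab, ab_prev = s.alpha_bar[t - 1], s.alpha_bar[t - 2]
        mean = (np.sqrt(ab_prev) * beta / (1 - ab) * z0
                + np.sqrt(1 - beta) * (1 - ab_prev) / (1 - ab) * z_t)
        var = s.beta_tilde[t - 1]
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3 * np.sqrt(var / n))
        se_var = var * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(draws.var(axis=0) - var) < 3 * se_var)

    def test_t_zero_is_out_of_range(self, rng):
        s = build_schedule(10)
        z = rng.standard_normal((1, 2))
        with pytest.raises(ScheduleError):
            posterior_target(z, z, 0, s, z)


class TestVarianceInterpolation:
    def test_endpoints_and_geometric_mean(self):
        s = build_schedule(100)
        d = 6
        for t in (2, 50, 100):
            beta, bt = s.beta[t - 1], s.beta_tilde[t - 1]
            np.testing.assert_allclose(
                interpolate_variance(np.ones(d), t, s), beta, rtol=1e-12)
            np.testing.assert_allclose(
                interpolate_variance(np.zeros(d), t, s), bt, rtol=1e-12)
            np.testing.assert_allclose(
                interpolate_variance(np.full(d, 0.5), t, s),
                np.sqrt(beta * bt), rtol=1e-12)

    def test_t1_lower_bound_clamps_to_beta1(self):
        s = build_schedule(100)
        np.testing.assert_allclose(
            interpolate_variance(np.zeros(4), 1, s), s.beta[0], rtol=1e-12)

    def test_out_of_range_s_rejected(self):
        s = build_schedule(10)
        with pytest.raises(ValueError):
            interpolate_variance(np.array([1.2]), 2, s)


class TestNllLoss:
    def test_exact_mean_leaves_only_log_variance_term(self):
        s = build_schedule(2, 0.999, 0.9999)
        target = np.random.default_rng(0).normal(size=(4, 3))
        out = DenoiserOutput(mu=target.copy(), s=np.ones((4, 3)))
        val = nll_loss(target, out, 2, s)
        # residual term vanishes; with beta_2 ~ 1 the loss is ~0
        assert val == pytest.approx(0.5 * np.log(s.beta[1]), rel=1e-12)
        assert abs(val) < 1e-4

    def test_matches_scalar_loop(self, rng):
        s = build_schedule(50)
        target = rng.normal(size=(6, 5))
        out = DenoiserOutput(mu=rng.normal(size=(6, 5)),
                             s=rng.uniform(size=(6, 5)))
        t = rng.integers(1, 51, size=6)
        val = nll_loss(target, out, t, s)
        acc = 0.0
        for i in range(6):
            beta = s.beta[t[i] - 1]
            bt = s.beta_tilde[t[i] - 1] if t[i] > 1 else s.beta[0]
            for j in range(5):
                sigma = np.exp(out.s[i, j] * np.log(beta)
                               + (1 - out.s[i, j]) * np.log(bt))
                acc += 0.5 * ((target[i, j] - out.mu[i, j]) ** 2 / sigma
                              + np.log(sigma))
        assert val == pytest.approx(acc / 30, rel=1e-6)

    def test_grid_search_minimizer_is_squared_residual(self, rng):
        # dL/dSigma = 0 at Sigma = e^2 for each element of the NLL
        residuals = rng.normal(size=8)
        grid = np.geomspace(1e-4, 1e2, 4001)
        for e in residuals:
            losses = e ** 2 / grid + np.log(grid)
            best = grid[np.argmin(losses)]
            assert best == pytest.approx(e ** 2, rel=2e-2)

    def test_analytic_kl_variant_is_nonnegative(self, rng):
        s = build_schedule(30)
        z0 = rng.normal(size=(5, 4))
        z_t = rng.normal(size=(5, 4))
        out = DenoiserOutput(mu=rng.normal(size=(5, 4)),
                             s=rng.uniform(size=(5, 4)))
        assert kl_loss(z0, z_t, out, 10, s) >= 0.0


def _toy_setup(seed=0, n=64, d=4, T=20):
    rng = np.random.default_rng(seed)
    cfg = ConditionConfig(n_genes=6, compound_dim=8, basal_dim=4, dose_dim=4,
                          time_dim=4, condition_dim=8, basal_hidden=(8,),
                          dose_hidden=(8,), time_hidden=(8,), fusion_hidden=(16,))
    encoder = ConditionEncoder(cfg, rng)
    schedule = build_schedule(T)
    denoiser = Denoiser(d, cfg.condition_dim, rng, T=T, hidden=(32, 32),
                        t_embed_dim=8, schedule=schedule)
    labels = rng.integers(0, 4, size=n)
    z0 = labels[:, None] * 0.8 + 0.1 * rng.standard_normal((n, d))
    z0 = (z0 - z0.mean(0)) / z0.std(0)
    conditions = {
        "basal": labels[:, None] * np.ones((n, 6)),
        "compound": np.eye(8)[labels * 2],
        "dose": rng.normal(size=n), "time": rng.normal(size=n)}
    return z0, conditions, schedule, encoder, denoiser


class TestTrainingAndSampling:
    @staticmethod
    def _frozen_batch_nll(z0, cond, sched, enc, den, seed=99):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, sched.T + 1, size=len(z0))
        z_t = forward_marginal(z0, t, sched, rng.standard_normal(z0.shape))
        target = posterior_target(z0, z_t, t, sched,
                                  rng.standard_normal(z0.shape))
        c = enc.forward(cond["basal"], cond["compound"], cond["dose"],
                        cond["time"])
        return nll_loss(target, den.forward(z_t, t, c), t, sched)

    def test_training_improves_frozen_batch_loss_and_reproduces(self):
        z0, cond, sched, enc, den = _toy_setup()
        before = self._frozen_batch_nll(z0, cond, sched, enc, den)
        cfg = DiffusionTrainConfig(n_steps=500, batch_size=32, log_every=20,
                                   seed=3)
        log1 = train_diffusion(z0, cond, sched, enc, den, cfg)
        after = self._frozen_batch_nll(z0, cond, sched, enc, den)
        assert after < before
        z0b, condb, schedb, encb, denb = _toy_setup()
        log2 = train_diffusion(z0b, condb, schedb, encb, denb, cfg)
        np.testing.assert_array_equal(log1["nll"].to_numpy(),
                                      log2["nll"].to_numpy())

    def test_true_conditions_beat_shuffled_conditions(self):
        z0, cond, sched, enc, den = _toy_setup(seed=1)
        cfg = DiffusionTrainConfig(n_steps=1200, batch_size=64, log_every=50,
                                   seed=3)
        log_true = train_diffusion(z0, cond, sched, enc, den, cfg)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(z0))
        cond_shuf = {k: v[perm] for k, v in cond.items()}
        _, _, sched2, enc2, den2 = _toy_setup(seed=1)
        log_shuf = train_diffusion(z0, cond_shuf, sched2, enc2, den2, cfg)
        assert (log_true["nll"].iloc[-5:].mean()
                <= log_shuf["nll"].iloc[-5:].mean())

    def test_analytic_kl_objective_trains_and_stays_nonnegative(self):
        z0, cond, sched, enc, den = _toy_setup(seed=2)
        cfg = DiffusionTrainConfig(n_steps=400, batch_size=32, log_every=20,
                                   objective="analytic_kl", seed=3)
        log = train_diffusion(z0, cond, sched, enc, den, cfg)
        assert (log["nll"] >= 0).all()
        assert log["nll"].iloc[-3:].mean() < log["nll"].iloc[:3].mean()

    def test_unknown_objective_rejected(self):
        with pytest.raises(ValueError, match="objective"):
            DiffusionTrainConfig(objective="elbo")

    def test_sampler_is_seed_deterministic(self):
        z0, cond, sched, enc, den = _toy_setup()
        sub = {k: v[:5] for k, v in cond.items()}
        a = sample(sub, sched, enc, den, n=3, seed=11)
        b = sample(sub, sched, enc, den, n=3, seed=11)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (15, 4)

    def test_null_denoiser_yields_centered_gaussianish_samples(self, rng):
        # mu = 0, s = 1 at every step: pure noise chain, wiring-level check
        class NullDenoiser:
            latent_dim = 3

            def forward(self, z_t, t, c):
                return DenoiserOutput(mu=np.zeros_like(z_t),
                                      s=np.ones_like(z_t))

        sched = build_schedule(50)
        cfg = ConditionConfig(n_genes=2, compound_dim=2, basal_dim=2,
                              dose_dim=2, time_dim=2, condition_dim=4,
                              basal_hidden=(4,), dose_hidden=(4,),
                              time_hidden=(4,), fusion_hidden=(4,))
        enc = ConditionEncoder(cfg, rng)
        cond = {"basal": np.zeros((1, 2)), "compound": np.zeros((1, 2)),
                "dose": np.zeros(1), "time": np.zeros(1)}
        z, states = sample(cond, sched, enc, NullDenoiser(), n=4000, seed=0,
                           trajectory=True)
        np.testing.assert_array_equal(z, 0.0)  # final step returns mu
        penult = states[-2]  # one noisy step remaining: N(0, beta_2)
        assert abs(penult.mean()) < 0.05
        assert penult.var() == pytest.approx(sched.beta[1], rel=0.15)
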