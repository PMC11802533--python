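"""Diffusion core: schedule invariants, forward/reverse kernels, loss."""

import numpy as np
import pytest

from perfdiff.diffusion import (NoiseSchedule, draw_training_gamma,
                                forward_marginal, forward_step, make_schedule,
                                reverse_step, sample, training_loss)
from perfdiff.phantom import NormalizationRecord


class TestSchedule:
    def test_default_schedule_invariants(self):
        s = make_schedule()
        assert s.T == 2000
        assert np.all((s.alpha > 0) & (s.alpha < 1))
        g = s.gamma
        assert np.all(np.diff(g) < 0) and np.all(g > 0)
        assert g[-1] < 1e-3
        np.testing.assert_allclose(s.sigma2, 1.0 - s.alpha, rtol=0, atol=1e-15)

    def test_near_zero_beta_leaves_images_unchanged(self):
        s = make_schedule(T=50, beta_start=1e-12, beta_end=1e-12)
        assert np.all(s.gamma > 1 - 1e-9)
        y0 = np.ones((4, 4))
        yt = forward_marginal(y0, 50, np.zeros((4, 4)), s)
        np.testing.assert_allclose(yt, y0, atol=1e-9)

    def test_constant_alpha_gamma_is_power(self):
        # alpha = 0.99 at every step: gamma_10 from an independent loop
        s = make_schedule(T=20, beta_start=0.01, beta_end=0.01)
        prod = 1.0
        for _ in range(10):
            prod *= 0.99
        assert s.gamma[9] == pytest.approx(prod, rel=1e-12)
        assert s.gamma[9] == pytest.approx(0.90438, abs=5e-6)

    @pytest.mark.parametrize("kw", [dict(T=0), dict(beta_start=0.0),
                                    dict(beta_end=1.0),
                                    dict(beta_start=0.5, beta_end=0.1)])
    def test_invalid_parameters(self, kw):
        with pytest.raises((ValueError,)):
            make_schedule(**{**dict(T=10, beta_start=1e-4, beta_end=0.1), **kw})

    def test_quadratic_kind_supported(self):
        s = make_schedule(T=10, beta_start=1e-4, beta_end=0.1, kind="quadratic")
        assert s.beta[0] == pytest.approx(1e-4) and s.beta[-1] == pytest.approx(0.1)


class _ZeroRng:
    """Stub generator forcing the noise draw to zero."""

    def standard_normal(self, shape):
        return np.zeros(shape)


class TestForward:
    schedule = make_schedule(T=100, beta_start=1e-4, beta_end=0.2)

    def test_step_with_zero_noise_scales_by_sqrt_alpha(self):
        y = np.full((3, 3), 2.0)
        out = forward_step(y, 7, self.schedule, _ZeroRng())
        np.testing.assert_allclose(out, np.sqrt(self.schedule.alpha[6]) * y)

    def test_step_from_zero_image_is_scaled_noise(self):
        rng = np.random.default_rng(0)
        z = np.random.default_rng(0).standard_normal((3, 3))
        out = forward_step(np.zeros((3, 3)), 5, self.schedule, rng)
        np.testing.assert_allclose(out, np.sqrt(1 - self.schedule.alpha[4]) * z)

    def test_marginal_with_zero_epsilon(self):
        y0 = np.arange(9.0).reshape(3, 3)
        out = forward_marginal(y0, 10, np.zeros((3, 3)), self.schedule)
        np.testing.assert_allclose(out, np.sqrt(self.schedule.gamma[9]) * y0)

    def test_marginal_algebraic_inverse(self, rng):
        y0 = rng.standard_normal((5, 5))
        eps = rng.standard_normal((5, 5))
        t = 42
        yt = forward_marginal(y0, t, eps, self.schedule)
        g = self.schedule.gamma[t - 1]
        back = (yt - np.sqrt(1 - g) * eps) / np.sqrt(g)
        np.testing.assert_allclose(back, y0, atol=1e-10)

    def test_terminal_state_is_nearly_pure_noise(self, rng):
        y0 = rng.standard_normal((8, 8))
        eps = rng.standard_normal((8, 8))
        yT = forward_marginal(y0, self.schedule.T, eps, self.schedule)
        gT = self.schedule.gamma[-1]
        bound = np.sqrt(gT) * np.abs(y0).max() + (1 - np.sqrt(1 - gT)) * np.abs(eps).max()
        assert np.abs(yT - eps).max() <= bound + 1e-12
        assert np.linalg.norm(yT - eps) < 0.05 * np.linalg.norm(eps)

    def test_iterated_steps_match_marginal_moments(self):
        """Monte-Carlo: iterating the one-step kernel t times reproduces the
        closed-form marginal's mean and variance within 4 standard errors."""
        sched = self.schedule
        rng = np.random.default_rng(2024)
        y0 = np.random.default_rng(1).standard_normal((8, 8))
        reps = 3000
        t = 30
        y = np.broadcast_to(y0, (reps, 8, 8)).copy()
        for step in range(1, t + 1):
            y = forward_step(y, step, sched, rng)
        g = sched.gamma[t - 1]
        resid = (y - np.sqrt(g) * y0).ravel()
        n = resid.size
        se_mean = np.sqrt((1 - g) / n)
        assert abs(resid.mean()) < 4 * se_mean
        se_var = (1 - g) * np.sqrt(2.0 / (n - 1))
        assert abs(resid.var() - (1 - g)) < 4 * se_var

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            forward_marginal(np.zeros((4, 4)), 3, np.zeros((2, 2)), self.schedule)

    @pytest.mark.parametrize("t", [0, 101])
    def test_step_index_out_of_range(self, t):
        with pytest.raises(IndexError):
            forward_step(np.zeros((2, 2)), t, self.schedule, _ZeroRng())


class TestReverse:
    schedule = make_schedule(T=100, beta_start=1e-4, beta_end=0.2)

    def test_zero_prediction_no_noise_rescales(self):
        y = np.full((3, 3), 0.5)
        t = 9
        out = reverse_step(y, t, np.zeros((3, 3)), self.schedule, inject_noise=False)
        np.testing.assert_allclose(out, y / np.sqrt(self.schedule.alpha[t - 1]))

    def test_perfect_denoiser_implied_y0_every_step(self, rng):
        """Passing the true injected noise, the one-step inversion recovers
        y0 at every t along the trajectory."""
        y0 = np.clip(rng.standard_normal((6, 6)), -1, 1)
        eps = rng.standard_normal((6, 6))
        for t in range(1, self.schedule.T + 1, 7):
            yt = forward_marginal(y0, t, eps, self.schedule)
            g = self.schedule.gamma[t - 1]
            y0_hat = (yt - np.sqrt(1 - g) * eps) / np.sqrt(g)
            assert np.abs(y0_hat - y0).max() < 1e-6

    def test_full_reverse_trajectory_recovers_y0(self, rng):
        """Noise-free reverse sweep with oracle noise predictions returns to
        y0 within 1e-4 relative error, over the full default schedule."""
        sched = make_schedule()   # T = 2000
        y0 = np.clip(rng.standard_normal((8, 8)), -1, 1)
        eps = rng.standard_normal((8, 8))
        y = forward_marginal(y0, sched.T, eps, sched)
        for t in range(sched.T, 0, -1):
            g = sched.gamma[t - 1]
            # oracle: the exact noise consistent with (y, y0) at level g
            eps_t = (y - np.sqrt(g) * y0) / np.sqrt(1 - g)
            y = reverse_step(y, t, eps_t, sched, inject_noise=False)
        rel = np.abs(y - y0).max() / np.abs(y0).max()
        assert rel < 1e-4

    def test_determinism_with_fixed_seed(self, rng):
        y = rng.standard_normal((4, 4))
        eh = rng.standard_normal((4, 4))
        a = reverse_step(y, 5, eh, self.schedule, np.random.default_rng(9))
        b = reverse_step(y, 5, eh, self.schedule, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_no_noise_injected_at_t1(self, rng):
        y = rng.standard_normal((4, 4))
        eh = rng.standard_normal((4, 4))
        a = reverse_step(y, 1, eh, self.schedule, np.random.default_rng(1),
                         inject_noise=True)
        b = reverse_step(y, 1, eh, self.schedule, inject_noise=False)
        np.testing.assert_array_equal(a, b)

    def test_t_zero_raises(self):
        with pytest.raises(IndexError):
            reverse_step(np.zeros((2, 2)), 0, np.zeros((2, 2)), self.schedule,
                         inject_noise=False)

    def test_clip_y0_bounds_the_implied_estimate(self, rng):
        y = 50.0 * rng.standard_normal((4, 4))
        t = 60
        out = reverse_step(y, t, np.zeros((4, 4)), self.schedule,
                           inject_noise=False, clip_y0=True)
        g = self.schedule.gamma[t - 1]
        # recomputed mean must correspond to a clipped y0 estimate
        a = self.schedule.alpha[t - 1]
        eps_eff = (y - out * np.sqrt(a)) * np.sqrt(1 - g) / (1 - a)
        y0_eff = (y - np.sqrt(1 - g) * eps_eff) / np.sqrt(g)
        assert np.abs(y0_eff).max() <= 1.0 + 1e-8


class TestSample:
    schedule = make_schedule(T=50, beta_start=1e-3, beta_end=0.3)

    @staticmethod
    def zero_model(x, y, gamma):
        return np.zeros_like(y)

    def test_zero_model_closed_form_product(self):
        out = sample(np.zeros((6, 6)), self.zero_model, self.schedule,
                     np.random.default_rng(4), inject_noise=False, clip_y0=False)
        yT = np.random.default_rng(4).standard_normal((6, 6))
        expected = np.clip(yT * np.prod(1.0 / np.sqrt(self.schedule.alpha)), -1, 1)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_same_seed_same_sample(self):
        a = sample(np.zeros((4, 4)), self.zero_model, self.schedule,
                   np.random.default_rng(11))
        b = sample(np.zeros((4, 4)), self.zero_model, self.schedule,
                   np.random.default_rng(11))
        np.testing.assert_array_equal(a, b)

    def test_output_respects_data_scale(self):
        norm = NormalizationRecord(kind="affine-to-[-1,1]", series_max=3.0)
        out = sample(np.zeros((4, 4)), self.zero_model, self.schedule,
                     np.random.default_rng(2), normalization=norm)
        assert out.min() >= 0.0 and out.max() <= 3.0

    def test_model_shape_mismatch_raises(self):
        def bad_model(x, y, gamma):
            return np.zeros((2, 2))
        with pytest.raises(ValueError):
            sample(np.zeros((4, 4)), bad_model, self.schedule,
                   np.random.default_rng(0))


class TestTrainingLoss:
    schedule = make_schedule(T=100, beta_start=1e-4, beta_end=0.2)

    def test_stub_returning_epsilon_gives_zero(self, rng):
        y0 = rng.standard_normal((4, 4))
        eps = rng.standard_normal((4, 4))

        def oracle(x, y_noisy, gamma):
            return (y_noisy - np.sqrt(gamma) * y0) / np.sqrt(1 - gamma)

        assert training_loss(oracle, np.zeros((4, 4)), y0, eps, 0.5) == pytest.approx(0, abs=1e-12)

    def test_constant_offset_gives_offset_magnitude(self, rng):
        y0 = rng.standard_normal((4, 4))
        eps = rng.standard_normal((4, 4))
        c = 0.37

        def stub(x, y_noisy, gamma):
            return (y_noisy - np.sqrt(gamma) * y0) / np.sqrt(1 - gamma) + c

        assert training_loss(stub, np.zeros((4, 4)), y0, eps, 0.3) == pytest.approx(c)

    def test_invariant_under_joint_flips_for_equivariant_stub(self, rng):
        y0 = rng.standard_normal((6, 6))
        eps = rng.standard_normal((6, 6))
        x = rng.standard_normal((6, 6))

        def equivariant(x_in, y_noisy, gamma):
            return 0.3 * y_noisy - 0.2 * x_in   # pointwise, hence flip-equivariant

        base = training_loss(equivariant, x, y0, eps, 0.6)
        flipped = training_loss(equivariant, x[::-1], y0[::-1], eps[::-1], 0.6)
        assert flipped == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize("g", [0.0, 1.0, -0.5])
    def test_gamma_out_of_open_interval(self, g):
        with pytest.raises(ValueError):
            training_loss(lambda *a: np.zeros((2, 2)), np.zeros((2, 2)),
                          np.zeros((2, 2)), np.zeros((2, 2)), g)


def test_training_gamma_draws_lie_in_schedule_range():
    sched = make_schedule(T=100, beta_start=1e-4, beta_end=0.2)
    rng = np.random.default_rng(0)
    g = draw_training_gamma(sched, rng, size=5000)
    assert set(np.unique(g)).issubset(set(sched.gamma))
    gc = draw_training_gamma(sched, rng, size=5000, continuous=True)
    assert gc.min() >= sched.gamma[-1] and gc.max() <= 1.0
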