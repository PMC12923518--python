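"""Belief-update recursions: single-step oracles, limits, and trajectory properties."""

import math

import numpy as np
import pytest

from lossvol.models import MODELS, ParameterError
from lossvol.perceptual import (
    INITIAL_STATE,
    TrajectoryError,
    hgf2_update,
    hgf3_update,
    k1_update,
    run_trajectory,
    rw_update,
)


class TestRescorlaWagner:
    @pytest.mark.parametrize(
        "v,u,alpha,expected",
        [(0.5, 1, 1.0, 1.0), (0.5, 1, 0.0, 0.5), (0.5, 1, 0.2, 0.6), (0.8, 0, 0.5, 0.4)],
    )
    def test_single_step(self, v, u, alpha, expected):
        assert rw_update(v, u, alpha) == pytest.approx(expected)

    def test_alpha_out_of_range(self):
        with pytest.raises(ParameterError, match="alpha"):
            rw_update(0.5, 1, 1.5)

    def test_full_learning_is_one_step_memory(self):
        u = np.array([1, 0, 0, 1, 1, 0])
        traj = run_trajectory("rw", {"alpha": 1.0}, u)
        np.testing.assert_allclose(traj.s_hat[1:], u[:-1])


class TestSuttonK1:
    def test_zero_meta_rate_reduces_to_rw(self):
        u = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 1])
        b0 = -1.2
        traj_k1 = run_trajectory("k1", {"k1_mu": 0.0, "k1_b0": b0}, u)
        traj_rw = run_trajectory("rw", {"alpha": math.exp(b0)}, u)
        np.testing.assert_allclose(traj_k1.s_hat, traj_rw.s_hat, atol=1e-12)
        assert np.allclose(traj_k1.learning_rate, math.exp(b0))

    def test_sustained_errors_raise_learning_rate(self):
        # 10 consecutive losses: same-sign prediction errors, so the adaptive
        # gain must be non-decreasing (independent step-through oracle below)
        u = np.ones(10, dtype=int)
        traj = run_trajectory("k1", {"k1_mu": 0.5, "k1_b0": -2.0}, u)
        assert np.all(np.diff(traj.learning_rate) >= -1e-12)
        # step-through oracle
        v, b, h = 0.5, -2.0, 0.0
        for t in range(10):
            assert traj.s_hat[t] == pytest.approx(v)
            v, b, h, rate = k1_update(v, b, h, 1, 0.5)
            assert traj.learning_rate[t] == pytest.approx(rate)

    def test_determinism(self):
        u = (np.arange(20) % 3 == 0).astype(int)
        p = {"k1_mu": 0.3, "k1_b0": -1.0}
        a = run_trajectory("k1", p, u)
        b = run_trajectory("k1", p, u)
        np.testing.assert_array_equal(a.s_hat, b.s_hat)


class TestHGF2:
    def test_single_step_oracle(self):
        # hand computation: mu2=0, sigma2=1, omega=-2, u=1:
        # sigma2hat = 1 + e^-2 = 1.13534, s_hat = 0.5,
        # pi2 = 1/1.13534 + 0.25 = 1.13080, mu2' = 0.5/1.13080 = 0.44217
        mu2, sigma2, s_hat, delta1, eps2 = hgf2_update(0.0, 1.0, 1, -2.0)
        assert s_hat == pytest.approx(0.5, abs=1e-4)
        assert mu2 == pytest.approx(0.4422, abs=1e-4)
        assert sigma2 == pytest.approx(0.8843, abs=1e-4)
        assert delta1 == pytest.approx(0.5, abs=1e-4)
        assert eps2 == pytest.approx(0.4422, abs=1e-4)

    def test_infinite_precision_freezes_beliefs(self):
        mu2, sigma2, *_ = hgf2_update(0.3, 1e-12, 1, -700.0)
        assert mu2 == pytest.approx(0.3, abs=1e-6)

    def test_update_size_monotone_in_omega(self):
        sizes = [abs(hgf2_update(0.2, 0.8, 1, w)[0] - 0.2) for w in (-6, -3, 0, 2)]
        assert all(a < b for a, b in zip(sizes, sizes[1:]))

    def test_variance_contracts_without_diffusion(self):
        # exp(omega) ~ 0: posterior variance can only shrink
        sigma2 = 1.0
        mu2 = 0.0
        for u in (1, 0, 1, 1, 0):
            mu2, new_sigma2, *_ = hgf2_update(mu2, sigma2, u, -700.0)
            assert new_sigma2 <= sigma2 + 1e-12
            sigma2 = new_sigma2

    def test_matches_delta_rule_with_fixed_variance(self):
        # holding sigma2 fixed, the update is a delta rule with rate 1/pi2
        mu2, sigma2, omega, u = 0.4, 0.7, -1.5, 1
        new_mu2, _, s_hat, delta1, _ = hgf2_update(mu2, sigma2, u, omega)
        pi2 = 1.0 / (sigma2 + math.exp(omega)) + s_hat * (1 - s_hat)
        assert new_mu2 == pytest.approx(mu2 + (1.0 / pi2) * delta1, rel=1e-12)

    def test_invalid_state(self):
        with pytest.raises(TrajectoryError):
            hgf2_update(0.0, -1.0, 1, -2.0)


def _hgf3_oracle(u_seq, omega, kappa, theta):
    """Independent step-through of the 3-level recursion (kept deliberately
    separate from the implementation)."""
    mu2, s2, mu3, s3 = 0.0, 1.0, 1.0, 1.0
    out = []
    for u in u_seq:
        sh = 1.0 / (1.0 + math.exp(-mu2))
        v = math.exp(kappa * mu3 + omega)
        s2hat = s2 + v
        pi2 = 1.0 / s2hat + sh * (1.0 - sh)
        mu2_new = mu2 + (u - sh) / pi2
        s2_new = 1.0 / pi2
        w2 = v / s2hat
        d2 = (s2_new + (mu2_new - mu2) ** 2) / s2hat - 1.0
        pi3 = 1.0 / (s3 + theta) + 0.5 * kappa**2 * w2 * (w2 + (2 * w2 - 1) * d2)
        mu3 = mu3 + 0.5 * kappa * w2 * d2 / pi3
        s3 = 1.0 / pi3
        mu2, s2 = mu2_new, s2_new
        out.append((mu2, s2, mu3, s3))
    return np.array(out)


class TestHGF3:
    def test_dual_implementation_on_alternating_sequence(self):
        u = np.array([1, 0] * 5)
        params = {"omega": -2.5, "kappa": 1.0, "theta": 0.05}
        traj = run_trajectory("hgf3", params, u)
        expected = _hgf3_oracle(u, -2.5, 1.0, 0.05)
        np.testing.assert_allclose(traj.mu2, expected[:, 0], atol=1e-10)
        np.testing.assert_allclose(traj.sigma2, expected[:, 1], atol=1e-10)
        np.testing.assert_allclose(traj.mu3, expected[:, 2], atol=1e-10)
        np.testing.assert_allclose(traj.sigma3, expected[:, 3], atol=1e-10)

    def test_small_kappa_decouples_to_hgf2(self):
        u = np.array([1, 1, 0, 1, 0, 0, 1])
        omega = -2.0
        t3 = run_trajectory("hgf3", {"omega": omega - 1e-8, "kappa": 1e-8, "theta": 0.1}, u)
        t2 = run_trajectory("hgf2", {"omega": omega}, u)
        np.testing.assert_allclose(t3.mu2, t2.mu2, atol=1e-6)

    def test_frozen_third_level(self):
        # with no step variance and (numerically) no level-3 uncertainty,
        # the volatility belief cannot move
        mu2, s2, mu3, s3 = 0.0, 1.0, 0.0, 1e-12
        for u in (1, 0, 1, 1):
            mu2, s2, mu3, s3, *_ = hgf3_update(mu2, s2, mu3, s3, u, -2.0, 1.0, 0.0)
            assert mu3 == pytest.approx(0.0, abs=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            hgf3_update(0.0, 1.0, 0.0, 1.0, 1, -2.0, -1.0, 0.1)


class TestTrajectories:
    def test_empty_outcomes(self):
        traj = run_trajectory("hgf2", {"omega": -3.0}, np.array([], dtype=int))
        assert len(traj) == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            run_trajectory("rw", {"alpha": 0.5}, np.array([0, 2]))

    @pytest.mark.parametrize("model", list(MODELS))
    def test_finite_within_five_prior_sds(self, model, rng):
        """All trajectories stay finite on a 200-trial task for parameters
        within +-5 prior SDs of the defaults (valid-precision HGF3 regimes)."""
        spec = MODELS[model]
        u = (rng.random(200) < 0.6).astype(int)
        for _ in range(20):
            x = spec.prior_means() + np.sqrt(spec.prior_vars()) * rng.uniform(-5, 5, spec.n_params)
            params = spec.to_native(x)
            try:
                traj = run_trajectory(model, params, u)
            except TrajectoryError:
                continue  # flagged invalid regimes are allowed to reject
            assert np.isfinite(traj.s_hat).all()
            assert np.all((traj.s_hat >= 0) & (traj.s_hat <= 1))

    def test_volatile_updates_larger_than_stable(self):
        """Mean |mu2 step| under HGF2 is larger in the volatile half (MC over
        50 schedules)."""
        import lossvol as lv

        stable, volatile = [], []
        for seed in range(50):
            s = lv.generate_schedule("stable_first", seed=seed)
            traj = run_trajectory("hgf2", {"omega": -2.0}, s.u_card1)
            steps = np.abs(np.diff(np.concatenate([[0.0], traj.mu2])))
            # trim the first 20 trials of each block (initial-uncertainty transient)
            stable.append(steps[20:100].mean())
            volatile.append(steps[120:200].mean())
        assert np.mean(volatile) > np.mean(stable)
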