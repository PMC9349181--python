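import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xlqg import (
    MomentTrajectory,
    generate_fixture_models,
    profiles,
    profiles_from_csv,
    profiles_to_csv,
    propagate_moments,
    solve,
)

from .oracles import kalman_gains
from .test_control_synthesis import classicize


def check_identities(traj: MomentTrajectory, tol: float = 1e-9) -> None:
    """The mean and variance recursions of x, xhat and e are mutually
    redundant; the decomposition identities must hold at every step."""
    scale_m = max(1.0, np.abs(traj.mean_x).max())
    assert np.abs(traj.mean_x - traj.mean_xhat - traj.mean_e).max() <= tol * scale_m
    recomposed = (
        traj.var_xhat
        + traj.var_e
        + traj.cov_xhat_e
        + np.transpose(traj.cov_xhat_e, (0, 2, 1))
    )
    scale_v = max(1.0, np.abs(traj.var_x).max())
    assert np.abs(traj.var_x - recomposed).max() <= tol * scale_v


class TestPropagateMoments:
    def test_noise_free_variances_identically_zero(self, noise_free_solution, noise_free_model):
        """With every noise scale zero, all spread is exactly zero at every
        step — zeros propagate exactly through the variance updates."""
        traj = propagate_moments(
            noise_free_model,
            noise_free_solution.control.L,
            noise_free_solution.filter.K,
        )
        for arr in (traj.var_x, traj.var_xhat, traj.var_e,
                    traj.cov_x_xhat, traj.cov_x_e, traj.cov_xhat_e):
            assert not arr.any()

    def test_zero_prior_covariance_keeps_error_mean_zero(self, basic_model, basic_solution):
        """The error-mean recursion is homogeneous; Sigma1 = 0 pins it at 0."""
        traj = propagate_moments(
            basic_model, basic_solution.control.L, basic_solution.filter.K
        )
        assert not traj.mean_e.any()

    def test_decomposition_identities_on_solved_models(self, basic_model, basic_solution, fixture_models):
        traj = propagate_moments(
            basic_model, basic_solution.control.L, basic_solution.filter.K
        )
        check_identities(traj)
        for m in fixture_models[:5]:
            res = solve(m, max_iter=200)
            check_identities(propagate_moments(m, res.control.L, res.filter.K))

    def test_variances_psd(self, basic_model, basic_solution):
        traj = propagate_moments(
            basic_model, basic_solution.control.L, basic_solution.filter.K
        )
        for arr in (traj.var_x, traj.var_xhat, traj.var_e):
            for V in arr:
                w = np.linalg.eigvalsh(V)
                assert w.min() >= -1e-8 * max(1.0, w.max())

    def test_error_variance_matches_kalman_in_classic_limit(self, fixture_models):
        """Without multiplicative noise, var[e] must reproduce both the
        textbook Kalman a-priori covariance and the filter pass's Sigma^e."""
        for m in fixture_models[:4]:
            classic = dataclasses.replace(classicize(m), xhat1=np.zeros(m.nx))
            res = solve(classic)
            traj = propagate_moments(classic, res.control.L, res.filter.K)
            _, Ps = kalman_gains(
                classic.A, classic.H, classic.Omega_xi, classic.Omega_omega,
                classic.Sigma1, classic.n_steps,
            )
            scale = max(np.abs(P).max() for P in Ps)
            for got, want, sig_e in zip(traj.var_e, Ps, res.filter.Sigma_e):
                np.testing.assert_allclose(got, want, atol=1e-10 * scale)
                np.testing.assert_allclose(got, sig_e, atol=1e-10 * scale)

    def test_filter_error_moment_agrees_at_optimum(self, basic_model, basic_solution):
        """At the converged optimum, Sigma^e from the filter recursion and
        var[e] from the moment recursion coincide."""
        traj = propagate_moments(
            basic_model, basic_solution.control.L, basic_solution.filter.K
        )
        Se = np.array(basic_solution.filter.Sigma_e)
        scale = np.abs(Se).max()
        assert np.abs(Se - traj.var_e).max() <= 1e-6 * scale

    def test_diverging_gains_raise(self, basic_model):
        huge = [np.full((1, 5), 1e200) for _ in range(50)]
        zero = [np.zeros((5, 3)) for _ in range(50)]
        with pytest.raises(FloatingPointError), np.errstate(all="ignore"):
            propagate_moments(basic_model, huge, zero)


class TestProfiles:
    def test_noise_free_speed_peak_near_mid_movement(self, noise_free_model, noise_free_solution, noise_free_params):
        traj = propagate_moments(
            noise_free_model,
            noise_free_solution.control.L,
            noise_free_solution.filter.K,
        )
        prof = profiles(traj, noise_free_params.dt)
        assert abs(prof.speed_peak_time - 0.25) <= noise_free_params.dt + 1e-12

    def test_all_zero_moments_tie_break_to_earliest(self):
        n, nx = 8, 2
        zeros = MomentTrajectory(
            *(np.zeros((n, nx)) for _ in range(3)),
            *(np.zeros((n, nx, nx)) for _ in range(6)),
        )
        prof = profiles(zeros, 0.01)
        assert prof.sd_peak_time == 0.0
        assert prof.speed_peak_time == 0.0
        assert not prof.pos_sd.any()

    def test_single_state_rejected(self):
        n = 4
        tiny = MomentTrajectory(
            *(np.zeros((n, 1)) for _ in range(3)),
            *(np.zeros((n, 1, 1)) for _ in range(6)),
        )
        with pytest.raises(ValueError):
            profiles(tiny, 0.01)

    def test_csv_round_trip_bit_exact(self, tmp_path, basic_model, basic_solution, basic_params):
        traj = propagate_moments(
            basic_model, basic_solution.control.L, basic_solution.filter.K
        )
        prof = profiles(traj, basic_params.dt)
        path = tmp_path / "profiles.csv"
        profiles_to_csv(prof, path)
        again = profiles_from_csv(path)
        np.testing.assert_array_equal(prof.time, again.time)
        np.testing.assert_array_equal(prof.speed, again.speed)
        np.testing.assert_array_equal(prof.pos_sd, again.pos_sd)
        assert again.speed_peak_time == prof.speed_peak_time


@settings(derandomize=True, max_examples=15, deadline=None)
@given(
    model_seed=st.integers(min_value=0, max_value=10_000),
    gain_seed=st.integers(min_value=0, max_value=10_000),
)
def test_identities_hold_for_arbitrary_gain_sequences(model_seed, gain_seed):
    """The decomposition identities are structural: they hold for any
    (even suboptimal, random) gain sequences, not just optimal ones."""
    m = generate_fixture_models(1, seed=model_seed)[0]
    rng = np.random.default_rng(gain_seed)
    L = [0.3 * rng.normal(size=(m.nu, m.nx)) for _ in range(m.n_steps - 1)]
    K = [0.3 * rng.normal(size=(m.nx, m.ny)) for _ in range(m.n_steps - 1)]
    check_identities(propagate_moments(m, L, K), tol=1e-8)
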