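"""Integration: RK4 correctness, mass balance, trajectory summaries."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import fermkin as fk
from fermkin.errors import ConfigError, NumericalError, ValidationError


class TestRk4Step:
    def test_no_inoculum_only_time_advances(self, params, yields):
        state = fk.BatchState(t=3.0, X=0.0, S=50.0, P=0.0, Z=0.0)
        out = fk.rk4_step(state, 0.5, params, yields)
        assert out.t == pytest.approx(3.5)
        assert (out.X, out.S, out.P, out.Z) == (0.0, 50.0, 0.0, 0.0)

    def test_matches_exponential_growth_at_saturating_substrate(self, yields):
        # with K_s -> 0 the growth law is a pure exponential in X
        p = fk.KineticParameters(mu_max0=0.244, K_s=1e-9, family="none")
        state = fk.BatchState(t=0.0, X=1.0, S=1000.0, P=0.0, Z=0.0)
        dt = 0.1
        out = fk.rk4_step(state, dt, p, yields)
        exact = math.exp(0.244 * dt)
        # one-step local error of a 4th-order method is O(dt^5)
        assert out.X == pytest.approx(exact, rel=1e-9)

    def test_fourth_order_one_step_convergence(self, params, yields):
        p_exact = fk.KineticParameters(mu_max0=0.244, K_s=1e-9, family="none")
        state = fk.BatchState(t=0.0, X=1.0, S=1000.0, P=0.0, Z=0.0)

        def one_step_err(dt):
            out = fk.rk4_step(state, dt, p_exact, yields)
            return abs(out.X - math.exp(0.244 * dt))

        ratio = one_step_err(0.8) / one_step_err(0.4)
        assert ratio == pytest.approx(32.0, rel=0.2)  # local error ~ dt^5

    def test_rejects_nonpositive_dt_and_nonfinite_state(self, params,
                                                        yields):
        state = fk.BatchState(t=0.0, X=1.0, S=100.0, P=0.0, Z=0.0)
        with pytest.raises(ConfigError):
            fk.rk4_step(state, 0.0, params, yields)
        bad = fk.BatchState.__new__(fk.BatchState)
        object.__setattr__(bad, "t", 2.0)
        for name, v in (("X", math.nan), ("S", 1.0), ("P", 0.0), ("Z", 0.0)):
            object.__setattr__(bad, name, v)
        with pytest.raises(NumericalError, match="t = 2.0"):
            fk.rk4_step(bad, 0.1, params, yields)


class TestSimulateBatch:
    def test_mass_balance_everywhere(self, params, yields, initial_100):
        traj = fk.simulate_batch(initial_100, params, yields, t_end=72,
                                 dt=0.01)
        consumed = initial_100.S - traj.S
        tol = 1e-6 * initial_100.S
        assert np.max(np.abs((traj.X - initial_100.X)
                             - yields.Y_xs * consumed)) <= tol
        assert np.max(np.abs(traj.P - yields.Y_ps * consumed)) <= tol
        assert np.max(np.abs(traj.Z - yields.Y_zs * consumed)) <= tol

    def test_complete_batch_reaches_stoichiometric_endpoint(
            self, params, yields, initial_100):
        traj = fk.simulate_batch(initial_100, params, yields, t_end=72,
                                 dt=0.01)
        assert traj.final.S == pytest.approx(0.0, abs=1e-6)
        assert traj.final.X == pytest.approx(1 + 0.28 * 100, rel=1e-6)
        assert traj.final.P == pytest.approx(42.0, rel=1e-6)
        assert traj.final.Z == pytest.approx(4.42, rel=1e-6)

    def test_monotone_variables_and_grid(self, params, yields, initial_100):
        traj = fk.simulate_batch(initial_100, params, yields, t_end=30,
                                 dt=0.05)
        assert len(traj) == 601
        assert np.all(np.diff(traj.t) > 0)
        assert np.all(np.diff(traj.S) <= 1e-12)
        assert np.all(np.diff(traj.X) >= -1e-12)
        assert np.all(np.diff(traj.P) >= -1e-12)
        assert np.all(np.diff(traj.Z) >= -1e-12)
        assert traj.S.min() >= 0.0

    def test_empty_substrate_stays_constant(self, params, yields):
        initial = fk.BatchState(t=0.0, X=1.0, S=0.0, P=0.0, Z=0.0)
        traj = fk.simulate_batch(initial, params, yields, t_end=10, dt=0.1)
        assert np.all(traj.X == 1.0)
        assert np.all(traj.S == 0.0)

    def test_inhibited_substrate_always_above_classical(self, params, yields,
                                                        initial_100):
        inhibited = fk.simulate_batch(initial_100, params, yields,
                                      t_end=40, dt=0.01)
        classical = fk.simulate_batch(initial_100,
                                      params.without_inhibition(), yields,
                                      t_end=40, dt=0.01)
        assert np.all(inhibited.S >= classical.S - 1e-9)

    def test_grid_refinement_fourth_order(self, params, yields, initial_100):
        def final_x(dt):
            return fk.simulate_batch(initial_100, params, yields, t_end=8.0,
                                     dt=dt).final.X

        ref = final_x(0.001)
        err_coarse = abs(final_x(0.16) - ref)
        err_fine = abs(final_x(0.08) - ref)
        assert err_coarse / err_fine == pytest.approx(16.0, rel=0.3)

    def test_exponential_oracle_high_resolution(self, yields):
        # K_s -> 0, no inhibition: X(t) = X0 exp(mu_max t) before exhaustion
        p = fk.KineticParameters(mu_max0=0.244, K_s=1e-9, family="none")
        initial = fk.BatchState(t=0.0, X=0.01, S=100.0, P=0.0, Z=0.0)
        traj = fk.simulate_batch(initial, p, yields, t_end=5.0, dt=0.001)
        exact = 0.01 * np.exp(0.244 * traj.t)
        assert np.max(np.abs(traj.X - exact) / exact) < 1e-8

    def test_agrees_with_independent_adaptive_integrator(
            self, params, yields, initial_100):
        traj = fk.simulate_batch(initial_100, params, yields, t_end=20,
                                 dt=0.01)

        def rhs(t, u):
            x, s, p_, z = u
            if s <= 0 or x <= 0:
                return [0.0, 0.0, 0.0, 0.0]
            mu = fk.modified_mu(params, s, z)
            dx = mu * x
            ds = -dx / yields.Y_xs
            return [dx, ds, -yields.Y_ps * ds, -yields.Y_zs * ds]

        sol = solve_ivp(rhs, (0, 20), [1.0, 100.0, 0.0, 0.0],
                        t_eval=[5, 10, 15, 20], rtol=1e-10, atol=1e-12)
        sampled = traj.sample([5, 10, 15, 20])
        np.testing.assert_allclose(
            sampled["biomass_g_L"].to_numpy(), sol.y[0], rtol=1e-7)
        np.testing.assert_allclose(
            sampled["glucose_g_L"].to_numpy(), sol.y[1], rtol=1e-7)

    def test_invalid_grid_rejected(self, params, yields, initial_100):
        with pytest.raises(ConfigError):
            fk.simulate_batch(initial_100, params, yields, t_end=-1, dt=0.1)
        with pytest.raises(ConfigError):
            fk.simulate_batch(initial_100, params, yields, t_end=1, dt=2.0)


class TestFermentationTime:
    def test_interpolated_crossing(self, params, yields):
        # synthetic trajectory with a known linear crossing
        t = np.array([0.0, 40.0, 42.0])
        S = np.array([100.0, 2.0, 0.5])
        traj = fk.Trajectory(t=t, X=np.zeros(3) + 1, S=S, P=np.zeros(3),
                             Z=np.zeros(3), params=params, yields=yields,
                             dt=math.nan)
        # threshold 1 g/L crossed between t=40 (S=2) and t=42 (S=0.5)
        expected = 40.0 + (2.0 - 1.0) / (2.0 - 0.5) * 2.0
        assert fk.fermentation_time(traj, 0.01) == pytest.approx(expected)

    def test_constant_substrate_never_completes(self, params, yields):
        t = np.arange(5.0)
        traj = fk.Trajectory(t=t, X=np.ones(5), S=np.full(5, 50.0),
                             P=np.zeros(5), Z=np.zeros(5), params=params,
                             yields=yields, dt=1.0)
        assert math.isnan(fk.fermentation_time(traj, 0.01))

    def test_threshold_one_is_time_zero(self, params, yields, initial_100):
        traj = fk.simulate_batch(initial_100, params, yields, t_end=1,
                                 dt=0.1)
        assert fk.fermentation_time(traj, 1.0) == 0.0


class TestModelDelay:
    def test_zero_when_both_classical(self, yields, initial_100):
        p = fk.KineticParameters(mu_max0=0.244, K_s=11.5, family="none")
        assert fk.model_delay(p, yields, initial_100) == pytest.approx(0.0)

    def test_nonnegative_and_monotone_in_s0(self, params, yields):
        delays = []
        for s0 in (100.0, 150.0, 200.0):
            initial = fk.BatchState(t=0.0, X=1.0, S=s0, P=0.0, Z=0.0)
            delays.append(fk.model_delay(params, yields, initial,
                                         t_end=100.0, dt=0.02))
        assert all(d >= 0 for d in delays)
        assert delays == sorted(delays)

    def test_vanishes_as_zm_grows(self, yields, initial_100):
        weak = fk.KineticParameters(mu_max0=0.244, K_s=11.5, Z_m=1e9,
                                    K_z=0.83, family="exponential")
        assert fk.model_delay(weak, yields, initial_100, dt=0.02) == \
            pytest.approx(0.0, abs=1e-6)


class TestTrajectoryExport:
    def test_roundtrip_to_file(self, params, yields, initial_100, tmp_path):
        traj = fk.simulate_batch(initial_100, params, yields, t_end=2,
                                 dt=0.5)
        path = tmp_path / "traj.csv"
        traj.write(path)
        from fermkin.io import read_timecourse
        back = read_timecourse(path)
        assert len(back) == len(traj)
        np.testing.assert_allclose(back["glucose_g_L"].to_numpy(), traj.S)

    def test_sampling_outside_horizon_rejected(self, params, yields,
                                               initial_100):
        traj = fk.simulate_batch(initial_100, params, yields, t_end=2,
                                 dt=0.5)
        with pytest.raises(ValidationError):
            traj.sample([0.0, 3.0])
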