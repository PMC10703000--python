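"""Unit and property tests for the coupled tumor/vascularization ODE model."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from evoimmune import (
    MU_V_VOLUME_SCALE,
    ModelParameters,
    ModelState,
    Trajectory,
    TreatmentSchedule,
    dose_effect,
    rhs,
    simulate,
    simulate_batch,
)


class TestDoseEffect:
    @pytest.mark.parametrize(
        "t, days, gamma, r, expected",
        [
            (5.0, (13.0, 14.0), 0.5, 0.3, 0.0),            # all doses in the future
            (13.0, (13.0,), 0.0091, 0.14, 0.0091),          # full effect at the dose instant
            (14.0, (13.0, 14.0), 0.1, 0.2, 0.1 * math.exp(-0.2) + 0.1),
        ],
    )
    def test_examples(self, t, days, gamma, r, expected):
        assert dose_effect(t, days, gamma, r) == pytest.approx(expected, rel=1e-12)

    def test_unsorted_days_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            dose_effect(5.0, (14.0, 13.0), 0.1, 0.2)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            dose_effect(5.0, (1.0,), -0.1, 0.2)

    def test_nonincreasing_between_doses(self):
        days = (7.0, 10.0, 13.0)
        ts = np.linspace(7.0, 9.99, 50)
        vals = [dose_effect(t, days, 0.5, 0.3) for t in ts]
        assert np.all(np.diff(vals) <= 0)
        assert min(vals) >= 0


class TestRhs:
    def test_no_vascularization_kills_death_term(self, params):
        sch = TreatmentSchedule(immuno_days=(7.0,))
        dT, dV = rhs(10.0, ModelState(T=50.0, V=0.0), params, sch)
        assert dT == pytest.approx(params.k_T * 50.0)

    def test_saturated_vascularization(self, params):
        sch = TreatmentSchedule()  # no evofosfamide doses
        dT, dV = rhs(10.0, ModelState(T=50.0, V=1.0), params, sch)
        assert dV == pytest.approx(-params.mu_V * 50.0 / MU_V_VOLUME_SCALE)

    def test_hand_computed_derivatives(self, params):
        # independent arithmetic oracle: one immuno and one evo dose at day 13
        sch = TreatmentSchedule(immuno_days=(13.0,), evo_days=(13.0,))
        t, T, V = 14.0, 100.0, 0.5
        kill = params.mu_T + params.gamma_i * math.exp(-params.r_i * 1.0)
        vasc = params.k_V + params.gamma_e * math.exp(-params.r_e * 1.0)
        want_dT = params.k_T * T - kill * T * V
        want_dV = vasc * (1 - V) - params.mu_V * (T / MU_V_VOLUME_SCALE) * V
        dT, dV = rhs(t, ModelState(T=T, V=V), params, sch)
        assert dT == pytest.approx(want_dT, rel=1e-12)
        assert dV == pytest.approx(want_dV, rel=1e-12)


class TestSimulate:
    def test_exponential_limit(self):
        # no death, no doses: pure exponential growth
        p = ModelParameters(k_T=0.33, k_V=0.094, mu_V=0.082, mu_T=0.0,
                            gamma_i=0.0, r_i=0.1, gamma_e=0.0, r_e=0.1)
        traj = simulate(p, TreatmentSchedule(), T0=100.0, V0=0.2, dt=0.01)
        exact = 100.0 * np.exp(p.k_T * (traj.times - traj.times[0]))
        assert np.max(np.abs(traj.T_series - exact) / exact) < 1e-6

    def test_vascular_saturation_limit(self):
        # mu_V = 0 and no evo doses: V relaxes to 1 at rate k_V
        p = ModelParameters(k_T=0.0, k_V=0.094, mu_V=0.0, mu_T=0.0,
                            gamma_i=0.0, r_i=0.1, gamma_e=0.0, r_e=0.1)
        traj = simulate(p, TreatmentSchedule(), T0=100.0, V0=0.3, dt=0.01)
        exact = 1.0 - 0.7 * np.exp(-p.k_V * (traj.times - traj.times[0]))
        assert np.max(np.abs(traj.V_series - exact)) < 1e-6

    def test_fourth_order_convergence(self, params, combo_schedule):
        def final_state(dt):
            tr = simulate(params, combo_schedule, 100.0, 0.2, dt=dt)
            return np.array([tr.T_series[-1], tr.V_series[-1]])

        ref = final_state(0.0125)
        err_coarse = np.abs(final_state(0.4) - ref).max()
        err_fine = np.abs(final_state(0.2) - ref).max()
        ratio = err_coarse / err_fine
        assert 8.0 < ratio < 40.0  # ~2^4 for a 4th-order scheme

    def test_matches_adaptive_reference(self, params, combo_schedule):
        traj = simulate(params, combo_schedule, 100.0, 0.2, dt=0.01)

        def f(t, y):
            return rhs(t, y, params, combo_schedule)

        sol = solve_ivp(f, (6.0, 39.0), [100.0, 0.2], rtol=1e-10, atol=1e-12,
                        dense_output=True, max_step=0.5)
        ref = sol.sol(traj.times)
        rel_T = np.max(np.abs(traj.T_series - ref[0]) / np.abs(ref[0]))
        assert rel_T < 1e-5
        assert np.max(np.abs(traj.V_series - ref[1])) < 1e-5

    def test_positivity_and_bounds(self, params, combo_schedule):
        traj = simulate(params, combo_schedule, 100.0, 0.0, dt=0.05)
        assert np.all(traj.T_series > 0)
        assert np.all((traj.V_series >= 0) & (traj.V_series <= 1))

    def test_monotone_immunotherapy_response(self, params, immuno_schedule):
        # stronger per-dose kill never increases the tumor volume anywhere
        base = simulate(params, immuno_schedule, 100.0, 0.3, dt=0.05)
        stronger = simulate(params.replace(gamma_i=5 * params.gamma_i),
                            immuno_schedule, 100.0, 0.3, dt=0.05)
        assert np.all(stronger.T_series <= base.T_series + 1e-12)

    def test_no_dose_equivalence_bitwise(self, params):
        # an empty schedule reproduces a hand-rolled control-only RK4 exactly
        traj = simulate(params, TreatmentSchedule(), 100.0, 0.2,
                        t_span=(6.0, 12.0), dt=0.1)

        def deriv(t, T, V):
            dT = params.k_T * T - params.mu_T * T * V
            dV = params.k_V * (1 - V) - params.mu_V * (T / MU_V_VOLUME_SCALE) * V
            return dT, dV

        grid = np.linspace(6.0, 12.0, 61)
        T, V = 100.0, 0.2
        Ts, Vs = [T], [V]
        for i in range(60):
            t, h = grid[i], grid[i + 1] - grid[i]
            k1 = deriv(t, T, V)
            k2 = deriv(t + h / 2, T + h / 2 * k1[0], V + h / 2 * k1[1])
            k3 = deriv(t + h / 2, T + h / 2 * k2[0], V + h / 2 * k2[1])
            k4 = deriv(t + h, T + h * k3[0], V + h * k3[1])
            T = T + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            V = V + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            Ts.append(T)
            Vs.append(V)
        np.testing.assert_array_equal(traj.T_series, np.array(Ts))
        np.testing.assert_array_equal(traj.V_series, np.array(Vs))

    def test_grid_contains_dose_and_output_days(self, params, combo_schedule):
        traj = simulate(params, combo_schedule, 100.0, 0.2, dt=0.07,
                        extra_days=[12.0, 17.0])
        for day in (7, 10, 12, 13, 14, 15, 16, 17):
            assert np.min(np.abs(traj.times - day)) < 1e-12

    def test_coarse_dt_warns_and_refines(self, params):
        sch = TreatmentSchedule(evo_days=(13.0, 13.5))
        with pytest.warns(UserWarning, match="inter-dose"):
            traj = simulate(params, sch, 100.0, 0.2, dt=1.0)
        assert np.max(np.diff(traj.times)) <= 1.0

    def test_batch_matches_single(self, params, combo_schedule):
        theta = np.vstack([params.to_array(), params.replace(k_T=0.2).to_array()])
        times, T, V = simulate_batch(theta, np.array([0.2, 0.4]), combo_schedule,
                                     100.0, dt=0.05)
        one = simulate(params, combo_schedule, 100.0, 0.2, dt=0.05)
        np.testing.assert_allclose(T[:, 0], one.T_series, rtol=1e-12)
        two = simulate(params.replace(k_T=0.2), combo_schedule, 100.0, 0.4, dt=0.05)
        np.testing.assert_allclose(V[:, 1], two.V_series, rtol=1e-12)

    def test_stiff_rows_flagged_not_poisoning_others(self, combo_schedule, params):
        # an extreme corner row fails; a calibrated row in the same batch is intact
        # fast growth with a strong V-coupling: mu_V*T/1000 reaches ~1e4/day
        bad = ModelParameters(k_T=0.4, k_V=0.01, mu_V=0.5, mu_T=0.0,
                              gamma_i=0.0, r_i=0.1, gamma_e=0.0, r_e=0.1)
        theta = np.vstack([params.to_array(), bad.to_array()])
        times, T, V, failed = simulate_batch(
            theta, 0.2, combo_schedule, 100.0, dt=0.1,
            max_substeps=2, return_failures=True)
        assert failed[1] and not failed[0]
        assert np.isnan(T[:, 1]).all()
        assert np.isfinite(T[:, 0]).all()


class TestDomainTypes:
    def test_parameters_reject_negative(self):
        with pytest.raises(ValueError):
            ModelParameters(k_T=-0.1, k_V=0.1, mu_V=0.1, mu_T=0.1,
                            gamma_i=0.1, r_i=0.1, gamma_e=0.1, r_e=0.1)

    def test_parameters_roundtrip(self, params):
        assert ModelParameters.from_array(params.to_array()) == params
        assert ModelParameters.from_dict(params.to_dict()) == params

    def test_schedule_rejects_unsorted(self):
        with pytest.raises(ValueError, match="increasing"):
            TreatmentSchedule(immuno_days=(10.0, 7.0))

    def test_schedule_outside_window(self):
        sch = TreatmentSchedule(immuno_days=(3.0,))
        with pytest.raises(ValueError, match="window"):
            sch.check_window((6.0, 39.0))

    def test_state_bounds(self):
        with pytest.raises(ValueError):
            ModelState(T=1.0, V=1.5)

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(times=[1.0, 1.0], T_series=[1.0, 1.0], V_series=[0.1, 0.1])
        tr = Trajectory(times=[1.0, 2.0], T_series=[1.0, 2.0], V_series=[0.1, 0.2])
        with pytest.raises(ValueError, match="grid"):
            tr.at(1.5)
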