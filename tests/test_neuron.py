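"""Single-cell model: gate kinetics, integration accuracy, excitability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eisync.errors import CalibrationError, PrcUndefinedError
from eisync.neuron import (NeuronParameters, NeuronState, calibrate_drive,
                           compute_prc, fi_curve, gate_time_constants,
                           membrane_derivative, simulate_single_neuron,
                           steady_rate, steady_state_gates)


class TestGateKinetics:
    def test_sigmoid_midpoints(self):
        g = steady_state_gates(-30.0)
        assert g.m == pytest.approx(0.5)
        assert g.n == pytest.approx(0.5)
        assert steady_state_gates(-53.0).h == pytest.approx(0.5)
        assert steady_state_gates(-39.0).z == pytest.approx(0.5)

    def test_m_inf_direct_evaluation(self):
        # 1 / (1 + e^(30/9.5)) evaluated with high-precision arithmetic
        assert steady_state_gates(-60.0).m == pytest.approx(
            0.0407813281, abs=1e-9)

    def test_time_constant_midpoints_and_tau_z(self):
        tau = gate_time_constants(-40.5)
        assert tau.h == pytest.approx(0.37 + 2.78 / 2)
        assert gate_time_constants(-27.0).n == pytest.approx(0.37 + 1.85 / 2)
        for v in (-120.0, -60.0, 0.0, 40.0):
            assert gate_time_constants(v).z == 75.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-120.0, max_value=40.0),
           st.floats(min_value=0.01, max_value=5.0))
    def test_gate_curves_bounded_and_monotone(self, v, dv):
        lo, hi = steady_state_gates(v), steady_state_gates(v + dv)
        for g in (lo, hi):
            for x in g:
                assert 0.0 < x < 1.0
        assert hi.m > lo.m and hi.n > lo.n and hi.z > lo.z
        assert hi.h < lo.h
        for tau in (gate_time_constants(v), gate_time_constants(v + dv)):
            assert tau.h > 0 and tau.n > 0 and tau.z > 0

    def test_non_finite_voltage_rejected(self):
        with pytest.raises(ValueError):
            steady_state_gates(np.nan)
        with pytest.raises(ValueError):
            gate_time_constants(np.inf)


class TestMembraneDerivative:
    def test_fixed_point_of_gates(self, type_i):
        g = steady_state_gates(-48.0)
        state = NeuronState(v=-48.0, h=float(g.h), n=float(g.n),
                            z=float(g.z))
        _, dh, dn, dz = membrane_derivative(state, type_i)
        assert dh == pytest.approx(0.0, abs=1e-14)
        assert dn == pytest.approx(0.0, abs=1e-14)
        assert dz == pytest.approx(0.0, abs=1e-14)

    def test_sodium_only_at_leak_reversal(self, type_i):
        # at V = E_l with n = z = 0 only the sodium term survives
        v = type_i.e_l
        g = steady_state_gates(v)
        state = NeuronState(v=v, h=float(g.h), n=0.0, z=0.0)
        dv, *_ = membrane_derivative(state, type_i)
        expected = -type_i.g_na * g.m ** 3 * g.h * (v - type_i.e_na)
        assert dv == pytest.approx(float(expected), rel=1e-12)

    def test_m_current_proportional_to_z(self, type_i, type_ii):
        state = NeuronState(v=-40.0, h=0.3, n=0.4, z=0.0)
        assert (membrane_derivative(state, type_ii)
                == membrane_derivative(state, type_i))


class TestSingleNeuron:
    def test_type_i_fires_spontaneously(self, type_i):
        r = simulate_single_neuron(type_i, 0.0)
        assert steady_rate(r.spike_times) > 0

    def test_type_i_silent_under_hyperpolarizing_drive(self, type_i):
        r = simulate_single_neuron(type_i, -0.2)
        assert steady_rate(r.spike_times) == 0.0

    def test_spike_times_strictly_increasing(self, type_i):
        r = simulate_single_neuron(type_i, 0.5)
        assert np.all(np.diff(r.spike_times) > 0)

    def test_step_halving_convergence(self, type_i):
        """Spike times at dt and dt/2 agree within 1 ms each over 1 s."""
        a = simulate_single_neuron(type_i, 0.5, duration=1000.0, dt=0.05)
        b = simulate_single_neuron(type_i, 0.5, duration=1000.0, dt=0.025)
        assert len(a.spike_times) == len(b.spike_times)
        assert np.max(np.abs(a.spike_times - b.spike_times)) < 1.0

    def test_gate_containment(self, type_i, type_ii):
        """h, n, z stay in [0, 1] at every recorded step."""
        for params, i_app in ((type_i, 1.0), (type_ii, 5.0)):
            r = simulate_single_neuron(
                params, i_app, duration=500.0,
                initial=NeuronState(v=-22.0, h=0.8, n=0.8, z=0.25))
            assert r.gates.min() >= 0.0 and r.gates.max() <= 1.0
            assert np.all(np.isfinite(r.v))

    def test_rk4_fourth_order_error_scaling(self, type_i):
        """Subthreshold global error shrinks ~16x when dt halves."""
        kw = dict(duration=100.0,
                  initial=NeuronState(v=-58.0, h=0.5, n=0.1, z=0.1))
        ref = simulate_single_neuron(type_i, -0.3, dt=0.05, **kw)
        coarse = simulate_single_neuron(type_i, -0.3, dt=0.4, **kw)
        fine = simulate_single_neuron(type_i, -0.3, dt=0.2, **kw)
        err_coarse = abs(coarse.v[-1] - ref.v[-1])
        err_fine = abs(fine.v[-1] - ref.v[-1])
        assert 8.0 < err_coarse / err_fine < 32.0

    def test_type_i_trajectory_independent_of_z(self, type_i):
        """With the M-current blocked, z carries no current: V identical."""
        lo = simulate_single_neuron(
            type_i, 0.3, duration=300.0,
            initial=NeuronState(v=-50.0, h=0.5, n=0.3, z=0.15))
        hi = simulate_single_neuron(
            type_i, 0.3, duration=300.0,
            initial=NeuronState(v=-50.0, h=0.5, n=0.3, z=0.25))
        np.testing.assert_array_equal(lo.v, hi.v)

    def test_cross_check_against_adaptive_integrator(self, type_ii):
        """One trace cross-checked against scipy's adaptive RK45."""
        solve_ivp = pytest.importorskip("scipy.integrate").solve_ivp

        p = type_ii
        i_app = 3.0

        def rhs(t, y):
            state = NeuronState(v=y[0], h=min(max(y[1], 0.0), 1.0),
                                n=min(max(y[2], 0.0), 1.0),
                                z=min(max(y[3], 0.0), 1.0))
            return membrane_derivative(state, p, i_app)

        init = NeuronState(v=-58.0, h=0.5, n=0.1, z=0.1)
        r = simulate_single_neuron(p, i_app, duration=60.0, dt=0.01,
                                   initial=init)
        sol = solve_ivp(rhs, (0.0, 60.0),
                        [init.v, init.h, init.n, init.z],
                        method="RK45", rtol=1e-10, atol=1e-12,
                        t_eval=r.t)
        assert np.max(np.abs(sol.y[0] - r.v)) < 0.1


class TestFICurve:
    def test_subthreshold_silent_and_monotone(self, type_i):
        currents, rates = fi_curve(type_i, np.arange(-0.4, 1.01, 0.1))
        assert np.all(rates[currents < -0.15] == 0.0)
        assert np.all(np.diff(rates) >= -1.0)

    def test_excitability_class_onset_signatures(self, type_i, type_ii):
        """Type I: arbitrarily low onset rate; Type II: bounded away."""
        grid_i = np.arange(-0.2, 0.0, 0.002)
        grid_ii = np.arange(1.0, 1.4, 0.002)
        _, r_i = fi_curve(type_i, grid_i)
        _, r_ii = fi_curve(type_ii, grid_ii)
        onset_i = r_i[r_i > 0].min()
        onset_ii = r_ii[r_ii > 0].min()
        assert onset_i < 5.0
        assert onset_ii > 2.0 * onset_i


class TestCalibration:
    def test_target_rate_reached(self, type_i):
        i45 = calibrate_drive(type_i, 45.0, tolerance=0.25)
        r = simulate_single_neuron(type_i, i45)
        assert 44.75 <= steady_rate(r.spike_times) <= 45.25

    def test_monotone_in_target(self, type_i):
        assert calibrate_drive(type_i, 55.0) > calibrate_drive(type_i, 45.0)

    def test_deterministic(self, type_ii):
        assert (calibrate_drive(type_ii, 50.0)
                == calibrate_drive(type_ii, 50.0))

    def test_unbracketable_target_raises(self, type_i):
        with pytest.raises(CalibrationError):
            calibrate_drive(type_i, 1000.0)


class TestPhaseResponse:
    def test_type_i_all_advances(self, type_i):
        prc = compute_prc(type_i, -0.05, pulse_amplitude=1.0, n_phases=25)
        assert prc.shifts.min() >= -0.01
        assert prc.shifts.max() > 0.01

    def test_type_ii_early_delay_lobe(self, type_ii):
        prc = compute_prc(type_ii, 1.5, pulse_amplitude=1.0, n_phases=25)
        assert prc.shifts[prc.phases < 0.5].min() < 0.0

    def test_zero_amplitude_zero_shifts(self, type_i):
        prc = compute_prc(type_i, 0.3, pulse_amplitude=0.0, n_phases=8)
        # T0 is a mean ISI while each probe measures one ISI, so shifts
        # are zero only up to the step-quantization of spike times
        assert np.max(np.abs(prc.shifts)) < 1e-3

    def test_undefined_for_silent_cell(self, type_i):
        with pytest.raises(PrcUndefinedError):
            compute_prc(type_i, -0.2)


def test_nonstandard_gks_warns():
    with pytest.warns(UserWarning):
        NeuronParameters(g_ks=0.7)
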