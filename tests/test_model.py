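"""Unit tests for the conductance-based model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermospike.model import (
    FICurve,
    InsufficientDataError,
    NeuronParameters,
    Q10Set,
    StimulusProtocol,
    compute_fi_curve,
    detect_spikes,
    evaluate_gating_rates,
    fit_sqrt,
    gate_steady_state,
    gate_time_constant,
    resting_state,
    simulate_voltage,
    sqrt_model,
    temperature_scale,
)


class TestGatingRates:
    def test_alpha_m_singularity_limit(self):
        # L'Hopital limit of 0.38 u / (1 - e^{-0.1 u}) at u = 0 is 3.8;
        # cross-checked by evaluating just off the singular point
        r = evaluate_gating_rates(-29.7)
        assert r["m"][0] == pytest.approx(3.8, abs=1e-9)
        for off in (+1e-6, -1e-6):
            r_off = evaluate_gating_rates(-29.7 + off)
            assert r_off["m"][0] == pytest.approx(3.8, abs=1e-5)

    def test_alpha_n_singularity_limit(self):
        r = evaluate_gating_rates(-45.7)
        assert r["n"][0] == pytest.approx(0.2, abs=1e-10)
        for off in (+1e-6, -1e-6):
            r_off = evaluate_gating_rates(-45.7 + off)
            assert r_off["n"][0] == pytest.approx(0.2, abs=1e-6)

    def test_b_inf_midpoint(self):
        # sigmoid midpoint raised to the 4th power
        assert gate_steady_state(-53.3)["b"] == pytest.approx(0.0625, abs=1e-12)

    def test_steady_state_and_tau_relations(self):
        r = evaluate_gating_rates(-50.0)
        for gate in ("m", "h", "n"):
            alpha, beta, x_inf, tau = r[gate]
            assert x_inf == pytest.approx(alpha / (alpha + beta))
            assert tau == pytest.approx(1.0 / (alpha + beta))

    def test_vectorized_evaluation(self):
        V = np.linspace(-100, 40, 57)
        r = evaluate_gating_rates(V)
        for gate in ("m", "h", "n"):
            assert r[gate][0].shape == V.shape
            assert np.all(r[gate][0] > 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            evaluate_gating_rates(np.nan)

    @given(st.floats(-120, 60))
    @settings(max_examples=50, deadline=None)
    def test_steady_states_in_unit_interval(self, V):
        for x in gate_steady_state(V).values():
            assert 0.0 <= float(x) <= 1.0


class TestTemperatureScale:
    def test_identity_at_delta_zero(self, ref_params):
        q = Q10Set(1.5, 1.7, 1.3, 1.9, 2.5, 3.0, 3.5, 2.2, 3.8)
        scaled, mult = temperature_scale(ref_params, q, 0.0)
        assert scaled == ref_params
        assert all(m == 1.0 for m in mult.values())

    def test_nernst_scaling_printed_value(self, ref_params):
        # E_Na = 55 mV, T0 = 18C, dT = +10 -> 55 * (1 + 10/291.15)
        q = Q10Set()
        scaled, _ = temperature_scale(ref_params, q, 10.0)
        assert scaled.E_Na == pytest.approx(55.0 * (1 + 10.0 / 291.15))
        assert scaled.E_Na == pytest.approx(56.889, abs=5e-4)
        # all reversals share the factor
        fac = 1 + 10.0 / 291.15
        assert scaled.E_K == pytest.approx(-72.0 * fac)
        assert scaled.E_L == pytest.approx(-17.0 * fac)

    def test_conductance_and_rate_factors(self, ref_params):
        q = Q10Set(g_K=1.2, n=4.0)
        scaled, mult = temperature_scale(ref_params, q, 10.0)
        assert scaled.g_K == pytest.approx(0.24)
        _, mult5 = temperature_scale(ref_params, Q10Set(n=4.0), 5.0)
        assert mult5["n"] == pytest.approx(2.0)  # 4^(5/10) = 2

    def test_xinf_invariant_tau_scaled(self, ref_params):
        # alpha and beta share one factor r: x_inf unchanged, tau / r
        q = Q10Set(m=3.0, h=2.0, n=4.0, a=2.5, b=3.5)
        _, mult = temperature_scale(ref_params, q, 10.0)
        V = -48.3
        tau_ref = gate_time_constant(V)
        for gate, r in mult.items():
            alpha_beta = evaluate_gating_rates(V)[gate]
            if len(alpha_beta) == 4:
                alpha, beta, x_inf, tau = alpha_beta
                assert (alpha * r) / (alpha * r + beta * r) == pytest.approx(x_inf)
            assert tau_ref[gate] / r == pytest.approx(
                tau_ref[gate] / (getattr(q, gate) ** 1.0))

    def test_q10set_validation(self):
        with pytest.raises(ValueError):
            Q10Set(g_L=0.0)
        with pytest.raises(ValueError):
            Q10Set(m=-1.0)
        assert Q10Set(1.2, 1.2, 1.2, 1.2, 2, 2, 2, 2, 2).is_physiological()
        assert not Q10Set(1.1, 1.2, 1.2, 1.2, 2, 2, 2, 2, 2).is_physiological()


class TestRestingState:
    def test_leak_only_rest_is_el(self):
        p = NeuronParameters(g_Na=0.0, g_K=0.0, g_A=0.0)
        v, gates = resting_state(p)
        assert v == pytest.approx(-17.0, abs=1e-7)

    def test_reference_resting_potential_plausible(self, ref_params):
        v, gates = resting_state(ref_params)
        assert -75.0 < v < -60.0
        assert all(0 <= g <= 1 for g in gates.values())


class TestSimulation:
    def test_zero_amplitude_stays_at_rest(self, ref_params, protocol):
        trace = simulate_voltage(ref_params, Q10Set(), 0.0, 0.0, protocol)
        assert np.ptp(trace.V) < 1e-3
        assert detect_spikes(trace.t, trace.V).size == 0

    def test_delta_zero_identity(self, ref_params, protocol):
        # scaling with dT=0 must reproduce the unscaled simulation exactly
        t1 = simulate_voltage(ref_params, Q10Set(), 0.0, 0.3, protocol)
        q = Q10Set(1.8, 1.4, 1.6, 1.2, 2.5, 3.5, 2.0, 4.0, 3.0)
        t2 = simulate_voltage(ref_params, q, 0.0, 0.3, protocol)
        np.testing.assert_array_equal(t1.V, t2.V)

    def test_membrane_equation_residual(self, ref_params, protocol):
        trace = simulate_voltage(ref_params, Q10Set(), 0.0, 0.0, protocol)
        # at rest the residual is limited only by the root-finder tolerance
        assert np.max(trace.membrane_residual(ref_params.C_m)[1:-1]) < 1e-3
        spiking = simulate_voltage(ref_params, Q10Set(), 0.0, 0.3, protocol)
        res = spiking.membrane_residual(ref_params.C_m)[1:-1]
        scale = np.max(np.abs(np.gradient(spiking.V, spiking.t)))
        # central differencing dominates the residual during spikes
        assert np.max(res) < 0.05 * scale

    def test_gating_bounds_on_grid_models(self, ref_params, protocol,
                                          random_grid_models):
        for q in random_grid_models[:4]:
            trace = simulate_voltage(ref_params, q, 10.0, 0.6, protocol)
            for g, x in trace.gates.items():
                assert np.all(x >= 0.0) and np.all(x <= 1.0), g

    def test_amplitude_validation(self, ref_params, protocol):
        with pytest.raises(ValueError):
            simulate_voltage(ref_params, Q10Set(), 0.0, -0.1, protocol)
        with pytest.raises(ValueError):
            simulate_voltage(ref_params, Q10Set(), 0.0, 0.1, protocol, dt=0.02)


class TestSolverOracle:
    """Fixed-step RK4 vs an adaptive stiff solver on the same system."""

    def test_spike_count_agreement(self, ref_params, protocol,
                                   random_grid_models):
        rng = np.random.default_rng(7)
        for q in random_grid_models[:6]:
            amp = float(rng.choice([0.2, 0.4, 0.6]))
            fixed = simulate_voltage(ref_params, q, 10.0, amp, protocol)
            stiff = simulate_voltage(ref_params, q, 10.0, amp, protocol,
                                     method="lsoda")
            n_fixed = detect_spikes(fixed.t, fixed.V).size
            n_stiff = detect_spikes(stiff.t, stiff.V).size
            assert abs(n_fixed - n_stiff) <= 1

    def test_voltage_agreement_outside_spikes(self, ref_params, protocol):
        fixed = simulate_voltage(ref_params, Q10Set(), 0.0, 0.3, protocol)
        stiff = simulate_voltage(ref_params, Q10Set(), 0.0, 0.3, protocol,
                                 method="lsoda")
        sub = (fixed.V < -45) & (stiff.V < -45)
        # exclude 2 ms around every spike of either trace (phase shifts
        # of the steep flanks would otherwise dominate)
        spikes = np.concatenate([detect_spikes(fixed.t, fixed.V),
                                 detect_spikes(stiff.t, stiff.V)])
        for ts in spikes:
            sub &= np.abs(fixed.t - ts) > 2.0
        assert np.max(np.abs(fixed.V[sub] - stiff.V[sub])) < 1.0

    def test_rheobase_bisection(self, ref_params, protocol):
        # bracket the rheobase by bisection on the spike count, then
        # confirm zero spikes just below it
        def n_spikes(amp):
            tr = simulate_voltage(ref_params, Q10Set(), 0.0, amp, protocol)
            sp = detect_spikes(tr.t, tr.V)
            return np.count_nonzero((sp >= protocol.t_start)
                                    & (sp < protocol.t_stop))

        lo, hi = 0.0, 0.10
        assert n_spikes(hi) > 0
        for _ in range(10):
            mid = 0.5 * (lo + hi)
            if n_spikes(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert n_spikes(lo) == 0
        assert n_spikes(hi) > 0
        # type I onset: low rate at threshold, decreasing toward rheobase
        rates = [n_spikes(hi + d) * 10.0 for d in (0.02, 0.005, 0.00125)]
        assert rates[0] < 50.0
        assert rates[0] >= rates[1] >= rates[2]


class TestDetectSpikes:
    def test_subthreshold_trace_empty(self):
        t = np.linspace(0, 10, 101)
        V = -60 + 5 * np.exp(-t)
        assert detect_spikes(t, V).size == 0

    def test_triangle_wave_crossings(self):
        # triangle between -50 and -10 crossing -30 upward 3 times at
        # analytically known points
        t = np.arange(0, 60.5, 0.5)
        period = 20.0
        phase = (t % period) / period
        V = np.where(phase < 0.5, -50 + 80 * phase, -10 - 80 * (phase - 0.5))
        spikes = detect_spikes(t, V, threshold=-30.0, lockout_ms=1.0)
        assert len(spikes) == 3
        np.testing.assert_allclose(spikes, [5.0, 25.0, 45.0], atol=1e-9)

    def test_touching_threshold_not_counted(self):
        t = np.arange(6.0)
        V = np.array([-50, -40, -30, -40, -50, -60.0])
        assert detect_spikes(t, V).size == 0

    def test_interpolated_crossing_time(self):
        t = np.array([0.0, 1.0])
        V = np.array([-40.0, -20.0])
        assert detect_spikes(t, V)[0] == pytest.approx(0.5)

    def test_lockout_suppresses_double_counts(self):
        t = np.arange(0, 2.0, 0.1)
        V = np.full_like(t, -60.0)
        V[3], V[5] = 0.0, 0.0   # two crossings 0.2 ms apart
        V[4] = -60.0
        assert len(detect_spikes(t, V, lockout_ms=1.0)) == 1
        assert len(detect_spikes(t, V, lockout_ms=0.1)) == 2

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            detect_spikes(np.empty(0), np.empty(0))


class TestFICurve:
    def test_reference_curve_properties(self, ref_params, protocol):
        fi = compute_fi_curve(ref_params, Q10Set(), 18.0, protocol)
        assert np.all(np.diff(fi.rates) >= 0)
        assert fi.rates[0] == 0.0            # 0.05 uA/mm^2 is subthreshold
        assert fi.r_squared > 0.97           # square-root fit quality
        assert fi.A > 0 and fi.I0 < 0.1
        # type I onset: rate at the smallest suprathreshold amplitude is low
        assert fi.rates[fi.rates > 0][0] < 50.0

    def test_exact_sqrt_samples_recovered(self):
        I = np.arange(0.05, 0.61, 0.05)
        rates = sqrt_model(I, 2.0, 0.1)
        A, I0, r2 = fit_sqrt(I, rates)
        assert A == pytest.approx(2.0, rel=1e-4)
        assert I0 == pytest.approx(0.1, rel=1e-4)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_curve_flagged(self, ref_params):
        proto = StimulusProtocol(amplitudes=(0.01, 0.02))
        fi = compute_fi_curve(ref_params, Q10Set(), 18.0, proto)
        assert np.all(fi.rates == 0)
        assert not fi.has_fit

    def test_single_nonzero_rate_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_sqrt(np.array([0.1, 0.2, 0.3]), np.array([0.0, 0.0, 50.0]))

    def test_heating_increases_slope(self, ref_params, protocol):
        cold = compute_fi_curve(ref_params, Q10Set(), 18.0, protocol)
        q = Q10Set(1.2, 1.2, 1.2, 1.2, 3.0, 3.0, 3.0, 3.0, 3.0)
        hot = compute_fi_curve(ref_params, q, 28.0, protocol)
        assert hot.A > cold.A

    def test_i0_bounded_by_first_spiking_amplitude(self):
        I = np.arange(0.05, 0.61, 0.05)
        rates = sqrt_model(I, 3.0, 0.12)
        _, I0, _ = fit_sqrt(I, rates)
        first_spiking = I[rates > 0][0]
        assert I0 < first_spiking

    def test_requires_two_amplitudes(self, ref_params):
        with pytest.raises(ValueError):
            compute_fi_curve(ref_params, Q10Set(), 18.0,
                             StimulusProtocol(amplitudes=(0.3,)))
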