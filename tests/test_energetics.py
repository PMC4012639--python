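"""Tests for the metabolic-cost observables."""

import numpy as np
import pytest

from thermospike.energetics import (
    NoSpikesError,
    charge_separation_efficiency,
    resting_costs,
    resting_costs_for_conductance_factors,
    resting_potential,
    sodium_load_per_spike,
    spiking_cost_q10,
)
from thermospike.model import (
    NeuronParameters,
    Q10Set,
    SimulationTrace,
    StimulusProtocol,
    detect_spikes,
    simulate_voltage,
    temperature_scale,
)


def _make_trace(t, i_na, i_k=None, i_a=None):
    z = np.zeros_like(t)
    return SimulationTrace(
        t=t, V=z - 60.0, gates={},
        I_Na=i_na,
        I_K=z if i_k is None else i_k,
        I_A=z if i_a is None else i_a,
        I_L=z, I_C=z, temperature=18.0, dt=float(t[1] - t[0]),
    )


class TestSodiumLoad:
    def test_rectangular_pulse_analytic(self):
        t = np.arange(0.0, 200.0, 0.001)
        i_na = np.where((t >= 60) & (t <= 80), -2.0, 0.0)   # area Q = 40
        trace = _make_trace(t, i_na)
        load = sodium_load_per_spike(trace, np.array([65.0, 75.0]), 50.0, 150.0)
        # trapezoid edge error of the discontinuous pulse is one sample
        assert load == pytest.approx(20.0, rel=1e-4)

    def test_no_spikes_raises(self):
        t = np.arange(0.0, 200.0, 0.1)
        trace = _make_trace(t, np.zeros_like(t))
        with pytest.raises(NoSpikesError):
            sodium_load_per_spike(trace, np.empty(0), 50.0, 150.0)

    def test_spikes_outside_window_not_counted(self):
        t = np.arange(0.0, 200.0, 0.1)
        trace = _make_trace(t, np.ones_like(t))
        with pytest.raises(NoSpikesError):
            # only a spike before the window
            sodium_load_per_spike(trace, np.array([10.0]), 50.0, 150.0)

    def test_reference_model_vs_adaptive_solver_oracle(self, ref_params,
                                                       protocol):
        fixed = simulate_voltage(ref_params, Q10Set(), 0.0, 0.3, protocol)
        stiff = simulate_voltage(ref_params, Q10Set(), 0.0, 0.3, protocol,
                                 method="lsoda")
        loads = []
        for tr in (fixed, stiff):
            spikes = detect_spikes(tr.t, tr.V)
            loads.append(sodium_load_per_spike(
                tr, spikes, protocol.t_start, protocol.t_stop))
        assert loads[0] == pytest.approx(loads[1], rel=0.01)

    def test_engine_load_matches_trace_integral(self, ref_params, protocol):
        # the sweep engine accumulates the same trapezoidal integral
        from thermospike.sweep import hot_observables

        _, loads_na, _, counts = hot_observables(
            ref_params, np.ones((1, 9)), 0.0, protocol)
        tr = simulate_voltage(ref_params, Q10Set(), 0.0, 0.3, protocol)
        spikes = detect_spikes(tr.t, tr.V)
        direct = sodium_load_per_spike(tr, spikes, protocol.t_start,
                                       protocol.t_stop)
        j = list(protocol.amplitudes).index(0.3)
        assert loads_na[0, j] / counts[0, j] == pytest.approx(direct, rel=1e-9)


class TestChargeSeparation:
    def test_disjoint_pulses_fully_efficient(self):
        t = np.arange(0.0, 100.0, 0.1)
        i_na = np.where((t >= 10) & (t < 20), -1.0, 0.0)
        i_k = np.where((t >= 30) & (t < 40), 1.0, 0.0)
        eff_na, eff_k = charge_separation_efficiency(
            _make_trace(t, i_na, i_k), (0.0, 99.0))
        assert eff_na == pytest.approx(1.0, abs=1e-2)
        assert eff_k == pytest.approx(1.0, abs=1e-2)

    def test_full_counterbalance_zero(self):
        t = np.arange(0.0, 100.0, 0.1)
        i = np.sin(t / 5.0) ** 2 + 0.1
        eff_na, eff_k = charge_separation_efficiency(
            _make_trace(t, -i, i), (0.0, 99.0))
        assert eff_na == pytest.approx(0.0, abs=1e-12)
        assert eff_k == pytest.approx(0.0, abs=1e-12)

    def test_half_overlap_analytic(self):
        t = np.arange(0.0, 100.0, 0.01)
        i_na = np.where((t >= 10) & (t < 30), -1.0, 0.0)
        i_k = np.where((t >= 20) & (t < 40), 1.0, 0.0)
        eff_na, eff_k = charge_separation_efficiency(
            _make_trace(t, i_na, i_k), (0.0, 99.0))
        assert eff_na == pytest.approx(0.5, abs=1e-3)
        assert eff_k == pytest.approx(0.5, abs=1e-3)

    def test_zero_reference_raises(self):
        t = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ValueError):
            charge_separation_efficiency(
                _make_trace(t, np.zeros_like(t)), (0.0, 9.0))

    def test_efficiency_bounds_and_complement_on_model_trace(self, ref_params,
                                                             protocol):
        tr = simulate_voltage(ref_params, Q10Set(), 0.0, 0.4, protocol)
        window = (protocol.t_start, protocol.t_stop + 20.0)
        eff_na, eff_k = charge_separation_efficiency(tr, window)
        assert 0.0 <= eff_na <= 1.0 and 0.0 <= eff_k <= 1.0
        # counterbalanced fraction + efficiency = 1 (Na referenced)
        mask = (tr.t >= window[0]) & (tr.t <= window[1])
        ina = np.abs(tr.I_Na)[mask]
        ik = np.abs(tr.I_K + tr.I_A)[mask]
        tt = tr.t[mask]
        overlap = np.trapezoid(np.minimum(ina, ik), tt)
        total = np.trapezoid(ina, tt)
        assert eff_na + overlap / total == pytest.approx(1.0, abs=1e-9)


class TestRestingPotential:
    def test_leak_only(self):
        p = NeuronParameters(g_Na=0.0, g_K=0.0, g_A=0.0)
        assert resting_potential(p) == pytest.approx(-17.0, abs=1e-7)

    def test_agrees_with_long_unstimulated_simulation(self, ref_params):
        # independent oracle: 500 ms of integration from a different state
        from thermospike._engine import rk4_trace
        from thermospike.model import gate_steady_state

        v0 = -60.0
        x = gate_steady_state(v0)
        y0 = np.array([v0, x["m"], x["h"], x["n"], x["a"], x["b"]])
        out = rk4_trace(y0, np.array(ref_params.conductances),
                        np.array(ref_params.reversals), ref_params.C_m,
                        np.ones(5), 0.0, 1e9, 2e9, 0.01, 50_000)
        assert out[-1, 0] == pytest.approx(resting_potential(ref_params),
                                           abs=0.1)

    def test_independent_of_gating_rate_q10s(self, ref_params):
        q1 = Q10Set(1.5, 1.5, 1.5, 1.5, 2.0, 2.0, 2.0, 2.0, 2.0)
        q2 = Q10Set(1.5, 1.5, 1.5, 1.5, 4.0, 4.0, 4.0, 4.0, 4.0)
        p1, _ = temperature_scale(ref_params, q1, 10.0)
        p2, _ = temperature_scale(ref_params, q2, 10.0)
        assert resting_potential(p1) == resting_potential(p2)

    def test_more_potassium_hyperpolarizes(self, ref_params):
        from dataclasses import replace

        v_prev = np.inf
        for f in (0.5, 0.8, 1.0, 1.5, 2.0):
            v = resting_potential(replace(ref_params, g_K=ref_params.g_K * f))
            assert v < v_prev
            v_prev = v

    def test_kirchhoff_residual(self, ref_params):
        v_r = resting_potential(ref_params)
        i_na, i_k = resting_costs(v_r, ref_params)
        i_l = ref_params.g_L * (ref_params.E_L - v_r)
        assert abs(i_na + i_k + i_l) < 1e-6

    def test_zero_sodium_conductance_zero_cost(self, ref_params):
        from dataclasses import replace

        p = replace(ref_params, g_Na=0.0)
        v_r = resting_potential(p)
        i_na, _ = resting_costs(v_r, p)
        assert i_na == 0.0


class TestRestingCostFractions:
    def test_rate_q10s_do_not_enter(self, ref_params):
        out1 = resting_costs_for_conductance_factors(
            ref_params, np.array([1.2, 1.5, 1.8, 2.0]), 0.0, 10.0)
        out2 = resting_costs_for_conductance_factors(
            ref_params, np.array([1.2, 1.5, 1.8, 2.0]), 0.0, 10.0)
        assert out1 == out2
        assert out1["q10_na_rest"] > 0

    def test_identity_q10s_still_change_costs_via_nernst(self, ref_params):
        # heating changes reversals even with conductance Q10s = 1
        out = resting_costs_for_conductance_factors(
            ref_params, np.ones(4), 0.0, 10.0)
        assert out["v_rest_cold"] != out["v_rest_hot"]


class TestSpikingCostQ10:
    def test_identical_loads(self):
        loads = np.array([1.0, 2.0, 3.0])
        assert spiking_cost_q10(loads, loads) == pytest.approx(1.0)

    def test_halved_loads(self):
        cold = np.array([2.0, 4.0])
        assert spiking_cost_q10(cold, cold / 2) == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        # mean(1/2, 3/4) = 0.625
        assert spiking_cost_q10(np.array([2.0, 4.0]),
                                np.array([1.0, 3.0])) == pytest.approx(0.625)

    def test_no_common_amplitude_flagged(self):
        out = spiking_cost_q10(np.array([np.nan, 2.0]),
                               np.array([1.0, np.nan]))
        assert np.isnan(out)

    def test_positive_loads_on_smoke_sweep(self, smoke_sweep):
        q10 = smoke_sweep.table["q10_spiking_cost"]
        assert np.isfinite(q10).all()
        assert (q10 > 0).all()
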