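"""Metabolic-cost observables of the model.

Spiking cost is the time integral of the sodium current magnitude ("sodium
load") from stimulus onset to 20 ms past stimulus offset, per spike.  An
alternative charge-separation efficiency measures the fraction of sodium
current not simultaneously counterbalanced by the total potassium current
(I_K + I_A); both measures exist potassium-referenced as well.  Resting
cost evaluates the steady ionic currents at the resting-potential fixed
point, which depends only on conductances and reversal potentials — never
on the gating-rate Q10s.

Sign convention: the physical I_Na is inward (negative in the membrane
equation's V - E_Na form for V < E_Na); all load integrals use |I_Na|
because the pump-load interpretation is a magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .model import (
    NeuronParameters,
    Q10Set,
    SimulationTrace,
    gate_steady_state,
    resting_state,
    temperature_scale,
)

__all__ = [
    "EnergyRecord",
    "sodium_load_per_spike",
    "charge_separation_efficiency",
    "resting_potential",
    "resting_costs",
    "resting_costs_for_conductance_factors",
    "spiking_cost_q10",
    "NoSpikesError",
]

#: integration window extends this far past stimulus offset (ms)
LOAD_TAIL_MS = 20.0


class NoSpikesError(ValueError):
    """Raised when a per-spike quantity is requested on a spikeless window."""


@dataclass
class EnergyRecord:
    """Energy observables of one model at one temperature."""

    loads_per_spike: np.ndarray          # per amplitude; NaN where no spikes
    efficiency_na: np.ndarray            # charge-separation, Na-referenced
    efficiency_k: np.ndarray
    v_rest: float
    i_na_rest: float
    i_k_rest: float


def _window_integral(t: np.ndarray, y: np.ndarray, t_lo: float, t_hi: float) -> float:
    """Trapezoidal integral of y over [t_lo, t_hi] on the trace grid."""
    mask = (t >= t_lo - 1e-9) & (t <= t_hi + 1e-9)
    if np.count_nonzero(mask) < 2:
        raise ValueError("integration window outside trace")
    return float(np.trapezoid(y[mask], t[mask]))


def sodium_load_per_spike(
    trace: SimulationTrace,
    spikes: np.ndarray,
    t_start: float,
    t_stop: float,
) -> float:
    """Sodium load per spike: integral of |I_Na| over
    [t_start, t_stop + 20 ms] divided by the spike count in that window."""
    t_hi = min(t_stop + LOAD_TAIL_MS, trace.t[-1])
    spikes = np.asarray(spikes, dtype=float)
    n_s = int(np.count_nonzero((spikes >= t_start) & (spikes <= t_hi)))
    if n_s == 0:
        raise NoSpikesError("no spikes in the integration window")
    return _window_integral(trace.t, np.abs(trace.I_Na), t_start, t_hi) / n_s


def charge_separation_efficiency(
    trace: SimulationTrace,
    window: tuple[float, float],
) -> tuple[float, float]:
    """Fractions of Na (resp. K) current not counterbalanced by the other.

    Na-referenced: integral of max(0, |I_Na| - |I_K,total|) over the
    window divided by the integral of |I_Na|; the potassium-referenced
    variant swaps the roles.  I_K,total = I_K + I_A.
    """
    t_lo, t_hi = window
    ina = np.abs(trace.I_Na)
    ik = np.abs(trace.I_K + trace.I_A)
    total_na = _window_integral(trace.t, ina, t_lo, t_hi)
    total_k = _window_integral(trace.t, ik, t_lo, t_hi)
    if total_na <= 0 or total_k <= 0:
        raise ValueError("reference integral is zero")
    eff_na = _window_integral(trace.t, np.maximum(ina - ik, 0.0), t_lo, t_hi) / total_na
    eff_k = _window_integral(trace.t, np.maximum(ik - ina, 0.0), t_lo, t_hi) / total_k
    return eff_na, eff_k


def resting_potential(params: NeuronParameters) -> float:
    """Resting-potential fixed point of the (already scaled) parameters."""
    v_rest, _ = resting_state(params)
    return v_rest


def resting_costs(v_rest: float, params: NeuronParameters) -> tuple[float, float]:
    """Steady sodium and potassium currents at the resting potential.

    ``I_Na,rest = g_Na(V_r) (E_Na - V_r)`` and
    ``I_K,rest = g_K(V_r) (E_K - V_r) + g_A(V_r) (E_A - V_r)`` with the
    gates at steady state.
    """
    x = gate_steady_state(v_rest)
    g_na = params.g_Na * float(x["m"]) ** 3 * float(x["h"])
    g_k = params.g_K * float(x["n"]) ** 4
    g_a = params.g_A * float(x["a"]) ** 3 * float(x["b"])
    i_na = g_na * (params.E_Na - v_rest)
    i_k = g_k * (params.E_K - v_rest) + g_a * (params.E_A - v_rest)
    return i_na, i_k


@lru_cache(maxsize=100_000)
def _resting_cost_cached(cond: tuple, rev: tuple) -> tuple[float, float, float]:
    from .sweep import _resting_fast

    vr, m, h, n, a, b = _resting_fast(*cond, *rev)
    g_na = cond[1] * m**3 * h
    g_k = cond[2] * n**4
    g_a = cond[3] * a**3 * b
    i_na = g_na * (rev[1] - vr)
    i_k = g_k * (rev[2] - vr) + g_a * (rev[3] - vr)
    return vr, i_na, i_k


def resting_costs_for_conductance_factors(
    params: NeuronParameters,
    cond_q10s: np.ndarray,
    delta_cold: float,
    delta_hot: float,
) -> dict:
    """Resting potential and resting costs at two temperatures, plus Q10s.

    Only the four conductance Q10s enter; gating-rate Q10s are irrelevant
    at the fixed point.  Q10s are computed on current magnitudes.
    """
    out = {}
    delta_t = delta_hot - delta_cold
    for tag, dt_ in (("cold", delta_cold), ("hot", delta_hot)):
        fac = np.asarray(cond_q10s, dtype=float) ** (dt_ / 10.0)
        cond = tuple(np.round(np.asarray(params.conductances) * fac, 14))
        e_fac = 1.0 + dt_ / (params.T0 + 273.15)
        rev = tuple(np.round(np.asarray(params.reversals) * e_fac, 14))
        vr, i_na, i_k = _resting_cost_cached(cond, rev)
        out[f"v_rest_{tag}"] = vr
        out[f"i_na_rest_{tag}"] = i_na
        out[f"i_k_rest_{tag}"] = i_k
    out["q10_na_rest"] = (
        abs(out["i_na_rest_hot"] / out["i_na_rest_cold"]) ** (10.0 / delta_t)
        if out["i_na_rest_cold"] != 0 else np.nan)
    out["q10_k_rest"] = (
        abs(out["i_k_rest_hot"] / out["i_k_rest_cold"]) ** (10.0 / delta_t)
        if out["i_k_rest_cold"] != 0 else np.nan)
    return out


def spiking_cost_q10(
    loads_per_spike_cold: np.ndarray,
    loads_per_spike_hot: np.ndarray,
    delta_t: float = 10.0,
) -> float:
    """Q10 of the spiking cost: per-amplitude Q10 of load/spike for the
    amplitudes suprathreshold at both temperatures, then the arithmetic
    mean.  Entries that are NaN (no spikes) at either temperature drop
    out; all-NaN input yields NaN (flagged missing)."""
    lc = np.asarray(loads_per_spike_cold, dtype=float)
    lh = np.asarray(loads_per_spike_hot, dtype=float)
    if lc.shape != lh.shape:
        raise ValueError("cold/hot records must align per amplitude")
    ok = np.isfinite(lc) & np.isfinite(lh) & (lc > 0) & (lh > 0)
    if not np.any(ok):
        return float("nan")
    return float(np.mean((lh[ok] / lc[ok]) ** (10.0 / delta_t)))


def energy_record(
    trace: SimulationTrace,
    spikes: np.ndarray,
    t_start: float,
    t_stop: float,
    scaled_params: NeuronParameters,
) -> EnergyRecord:
    """Convenience bundle of all energy observables for one trace."""
    t_hi = min(t_stop + LOAD_TAIL_MS, trace.t[-1])
    try:
        load = sodium_load_per_spike(trace, spikes, t_start, t_stop)
    except NoSpikesError:
        load = float("nan")
    eff_na, eff_k = charge_separation_efficiency(trace, (t_start, t_hi))
    v_rest = resting_potential(scaled_params)
    i_na, i_k = resting_costs(v_rest, scaled_params)
    return EnergyRecord(
        loads_per_spike=np.array([load]),
        efficiency_na=np.array([eff_na]),
        efficiency_k=np.array([eff_k]),
        v_rest=v_rest,
        i_na_rest=i_na,
        i_k_rest=i_k,
    )
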