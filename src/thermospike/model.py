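"""Temperature-dependent Connor-Stevens spike-generation model.

Single-compartment conductance-based model with a transient sodium current
(gates m, h), a delayed-rectifier potassium current (gate n), an A-type
potassium current (gates a, b) and a passive leak.  Membrane equation::

    C_m dV/dt = I_C - I_L - I_Na - I_K - I_A

Units are mutually consistent throughout: mV, ms, mS/mm^2, uA/mm^2 and
nF/mm^2 (mS/mm^2 * mV = uA/mm^2; uA/nF = mV/ms * 1000).

Temperature enters through nine Q10 coefficients (four peak conductances,
five gating-rate factors) plus a linear-in-absolute-temperature scaling of
the reversal potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, least_squares

__all__ = [
    "NeuronParameters",
    "Q10Set",
    "StimulusProtocol",
    "SimulationTrace",
    "FICurve",
    "GATE_NAMES",
    "CONDUCTANCE_NAMES",
    "evaluate_gating_rates",
    "gate_steady_state",
    "gate_time_constant",
    "temperature_scale",
    "resting_state",
    "simulate_voltage",
    "detect_spikes",
    "compute_fi_curve",
    "fit_sqrt",
    "InsufficientDataError",
    "SimulationBlowupError",
]

GATE_NAMES = ("m", "h", "n", "a", "b")
CONDUCTANCE_NAMES = ("g_L", "g_Na", "g_K", "g_A")

#: width of the series window used at the removable singularities of
#: alpha_m and alpha_n (mV)
_SINGULARITY_EPS = 1e-6


class InsufficientDataError(ValueError):
    """Raised when a fit is requested on too few suprathreshold samples."""


class SimulationBlowupError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""

    def __init__(self, time_ms: float):
        self.time_ms = time_ms
        super().__init__(f"non-finite state at t = {time_ms:.3f} ms")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParameters:
    """Biophysical parameters of the model at a reference temperature.

    Defaults are the original Connor-Stevens values defined at 18 degC.
    ``C_m`` (nF/mm^2) is not part of the published parameter set; the
    conventional 10 nF/mm^2 (= 1 uF/cm^2) is adopted.
    """

    g_L: float = 0.003
    g_Na: float = 1.2
    g_K: float = 0.2
    g_A: float = 0.477
    E_L: float = -17.0
    E_Na: float = 55.0
    E_K: float = -72.0
    E_A: float = -75.0
    C_m: float = 10.0
    T0: float = 18.0

    def __post_init__(self) -> None:
        for name in CONDUCTANCE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")

    @property
    def conductances(self) -> tuple[float, float, float, float]:
        return (self.g_L, self.g_Na, self.g_K, self.g_A)

    @property
    def reversals(self) -> tuple[float, float, float, float]:
        return (self.E_L, self.E_Na, self.E_K, self.E_A)


@dataclass(frozen=True)
class Q10Set:
    """Nine temperature coefficients indexing one model on the grid.

    Four conductance Q10s (physiological range [1.2, 2.0]) and five
    gating-rate Q10s (range [2.0, 4.0]); a gate's opening and closing
    rates share one coefficient.
    """

    g_L: float = 1.0
    g_Na: float = 1.0
    g_K: float = 1.0
    g_A: float = 1.0
    m: float = 1.0
    h: float = 1.0
    n: float = 1.0
    a: float = 1.0
    b: float = 1.0

    CONDUCTANCE_RANGE = (1.2, 2.0)
    GATE_RANGE = (2.0, 4.0)

    def __post_init__(self) -> None:
        for name in CONDUCTANCE_NAMES + GATE_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"Q10({name}) must be > 0")

    @property
    def conductance_values(self) -> tuple[float, float, float, float]:
        return (self.g_L, self.g_Na, self.g_K, self.g_A)

    @property
    def gate_values(self) -> tuple[float, float, float, float, float]:
        return (self.m, self.h, self.n, self.a, self.b)

    def is_physiological(self) -> bool:
        lo_g, hi_g = self.CONDUCTANCE_RANGE
        lo_x, hi_x = self.GATE_RANGE
        return all(lo_g <= q <= hi_g for q in self.conductance_values) and all(
            lo_x <= q <= hi_x for q in self.gate_values
        )

    def as_array(self) -> np.ndarray:
        return np.array(self.conductance_values + self.gate_values)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "Q10Set":
        v = tuple(float(x) for x in values)
        if len(v) != 9:
            raise ValueError("expected 9 Q10 values")
        return cls(*v)


@dataclass(frozen=True)
class StimulusProtocol:
    """Step-current protocol: silent pre window, stimulus, silent post window."""

    pre_ms: float = 50.0
    stim_ms: float = 100.0
    post_ms: float = 50.0
    amplitudes: tuple[float, ...] = tuple(
        round(0.05 * k, 10) for k in range(1, 13)
    )

    def __post_init__(self) -> None:
        if min(self.pre_ms, self.stim_ms, self.post_ms) <= 0:
            raise ValueError("durations must be > 0")
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))

    @property
    def t_start(self) -> float:
        return self.pre_ms

    @property
    def t_stop(self) -> float:
        return self.pre_ms + self.stim_ms

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.stim_ms + self.post_ms


@dataclass
class SimulationTrace:
    """Full state trajectory of one simulation on a uniform time grid."""

    t: np.ndarray
    V: np.ndarray
    gates: dict[str, np.ndarray]
    I_Na: np.ndarray
    I_K: np.ndarray
    I_A: np.ndarray
    I_L: np.ndarray
    I_C: np.ndarray
    temperature: float
    dt: float

    def membrane_residual(self, C_m: float = 10.0) -> np.ndarray:
        """|C_m dV/dt - (I_C - I_L - I_Na - I_K - I_A)| via central differences."""
        dVdt = np.gradient(self.V, self.t)
        rhs = 1000.0 / C_m * (self.I_C - self.I_L - self.I_Na - self.I_K - self.I_A)
        return np.abs(dVdt - rhs)


@dataclass
class FICurve:
    """Firing rate vs injected current at one temperature, with sqrt fit."""

    temperature: float
    currents: np.ndarray
    rates: np.ndarray
    A: float | None = None
    I0: float | None = None
    r_squared: float | None = None

    @property
    def has_fit(self) -> bool:
        return self.A is not None

    def predict(self, currents: np.ndarray) -> np.ndarray:
        if not self.has_fit:
            raise ValueError("curve has no fit attached")
        return sqrt_model(np.asarray(currents, dtype=float), self.A, self.I0)


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------

def _alpha_m(V):
    u = V + 29.7
    out = np.where(
        np.abs(u) < _SINGULARITY_EPS,
        3.8 + 0.19 * u,
        0.38 * u / (1.0 - np.exp(-0.1 * np.where(np.abs(u) < _SINGULARITY_EPS, 1.0, u))),
    )
    return out


def _beta_m(V):
    return 15.2 * np.exp(-0.0556 * (V + 54.7))


def _alpha_h(V):
    return 0.266 * np.exp(-0.05 * (V + 48.0))


def _beta_h(V):
    return 3.8 / (1.0 + np.exp(-0.1 * (V + 18.0)))


def _alpha_n(V):
    u = V + 45.7
    out = np.where(
        np.abs(u) < _SINGULARITY_EPS,
        0.2 + 0.01 * u,
        0.02 * u / (1.0 - np.exp(-0.1 * np.where(np.abs(u) < _SINGULARITY_EPS, 1.0, u))),
    )
    return out


def _beta_n(V):
    return 0.25 * np.exp(-0.0125 * (V + 55.7))


def _tau_a(V):
    return 0.3632 + 1.158 / (1.0 + np.exp(0.0497 * (V + 55.96)))


def _a_inf(V):
    # the printed expression marginally exceeds 1 around +40 mV (by ~7e-4);
    # clamped so the gating state stays a true fraction
    return np.minimum(
        (
            0.0761 * np.exp(0.0314 * (V + 94.22))
            / (1.0 + np.exp(0.0346 * (V + 1.17)))
        ) ** (1.0 / 3.0),
        1.0,
    )


def _tau_b(V):
    return 1.24 + 2.678 / (1.0 + np.exp(0.0624 * (V + 50.0)))


def _b_inf(V):
    return (1.0 / (1.0 + np.exp(0.0688 * (V + 53.3)))) ** 4


def evaluate_gating_rates(V):
    """Evaluate all gating kinetics at membrane voltage ``V`` (mV).

    Returns a dict keyed by gate name.  For m, h, n the entries hold
    ``(alpha, beta, x_inf, tau)`` (alpha, beta in 1/ms, tau in ms); for
    a, b — whose kinetics are published as steady state and time
    constant — the entries hold ``(x_inf, tau)``.  The removable
    singularities of alpha_m and alpha_n are evaluated by their
    first-order series.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage must be finite")
    out = {}
    for gate, (fa, fb) in {
        "m": (_alpha_m, _beta_m),
        "h": (_alpha_h, _beta_h),
        "n": (_alpha_n, _beta_n),
    }.items():
        alpha, beta = fa(V), fb(V)
        out[gate] = (alpha, beta, alpha / (alpha + beta), 1.0 / (alpha + beta))
    out["a"] = (_a_inf(V), _tau_a(V))
    out["b"] = (_b_inf(V), _tau_b(V))
    return out


def gate_steady_state(V):
    """x_inf for all five gates at voltage V, as a dict."""
    r = evaluate_gating_rates(V)
    return {g: (r[g][2] if len(r[g]) == 4 else r[g][0]) for g in GATE_NAMES}


def gate_time_constant(V):
    """tau_x for all five gates at voltage V (ms, at reference temperature)."""
    r = evaluate_gating_rates(V)
    return {g: (r[g][3] if len(r[g]) == 4 else r[g][1]) for g in GATE_NAMES}


# ---------------------------------------------------------------------------
# temperature scaling
# ---------------------------------------------------------------------------

def temperature_scale(
    params: NeuronParameters, q10s: Q10Set, delta_t: float
) -> tuple[NeuronParameters, dict[str, float]]:
    """Scale a parameter set from T0 to T0 + ``delta_t``.

    Peak conductances are multiplied by ``Q10 ** (delta_t / 10)``; every
    reversal potential by ``1 + delta_t / (T0 + 273.15)`` (linearization of
    the Nernst relation in absolute temperature); and each gate's opening
    and closing rates share the factor ``Q10_x ** (delta_t / 10)``, which
    divides tau and leaves x_inf untouched.

    Returns the scaled parameters and the per-gate rate multipliers.
    """
    if not math.isfinite(delta_t):
        raise ValueError("delta_t must be finite")
    e_fac = 1.0 + delta_t / (params.T0 + 273.15)
    g_fac = {g: getattr(q10s, g) ** (delta_t / 10.0) for g in CONDUCTANCE_NAMES}
    scaled = replace(
        params,
        g_L=params.g_L * g_fac["g_L"],
        g_Na=params.g_Na * g_fac["g_Na"],
        g_K=params.g_K * g_fac["g_K"],
        g_A=params.g_A * g_fac["g_A"],
        E_L=params.E_L * e_fac,
        E_Na=params.E_Na * e_fac,
        E_K=params.E_K * e_fac,
        E_A=params.E_A * e_fac,
    )
    rate_mult = {g: getattr(q10s, g) ** (delta_t / 10.0) for g in GATE_NAMES}
    return scaled, rate_mult


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

def _net_current(V: float, p: NeuronParameters) -> float:
    """Total membrane current at steady-state gating (uA/mm^2, inward > 0)."""
    x = gate_steady_state(V)
    i_l = p.g_L * (p.E_L - V)
    i_na = p.g_Na * float(x["m"]) ** 3 * float(x["h"]) * (p.E_Na - V)
    i_k = p.g_K * float(x["n"]) ** 4 * (p.E_K - V)
    i_a = p.g_A * float(x["a"]) ** 3 * float(x["b"]) * (p.E_A - V)
    return i_l + i_na + i_k + i_a


def resting_state(params: NeuronParameters, xtol: float = 1e-9):
    """I=0 fixed point: resting potential and steady-state gate values.

    Solves the zero of the net steady-state current by bracketed root
    finding on the interval spanned by the reversal potentials.  The
    result is independent of all gating-rate Q10s by construction.
    """
    lo = min(params.reversals)
    hi = max(params.reversals)
    f_lo, f_hi = _net_current(lo, params), _net_current(hi, params)
    if f_lo * f_hi > 0:
        raise ValueError("no sign change of the net current in the reversal bracket")
    v_rest = brentq(_net_current, lo, hi, args=(params,), xtol=xtol)
    gates = {g: float(v) for g, v in gate_steady_state(v_rest).items()}
    return float(v_rest), gates


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _derivatives(V, m, h, n, a, b, i_c, p: NeuronParameters, rm, rh, rn, ra, rb):
    """Right-hand side of the 6-state system (scalar or array)."""
    i_l = p.g_L * (V - p.E_L)
    i_na = p.g_Na * m**3 * h * (V - p.E_Na)
    i_k = p.g_K * n**4 * (V - p.E_K)
    i_a = p.g_A * a**3 * b * (V - p.E_A)
    dV = 1000.0 / p.C_m * (i_c - i_l - i_na - i_k - i_a)
    am, bm = _alpha_m(V), _beta_m(V)
    ah, bh = _alpha_h(V), _beta_h(V)
    an, bn = _alpha_n(V), _beta_n(V)
    dm = rm * (am * (1.0 - m) - bm * m)
    dh = rh * (ah * (1.0 - h) - bh * h)
    dn = rn * (an * (1.0 - n) - bn * n)
    da = ra * (_a_inf(V) - a) / _tau_a(V)
    db = rb * (_b_inf(V) - b) / _tau_b(V)
    return dV, dm, dh, dn, da, db


def simulate_voltage(
    params: NeuronParameters,
    q10s: Q10Set,
    delta_t: float,
    amplitude: float,
    protocol: StimulusProtocol | None = None,
    dt: float = 0.01,
    method: str = "rk4",
) -> SimulationTrace:
    """Integrate the 6-state system for one step-current stimulus.

    The current ``amplitude`` (uA/mm^2) is applied only during the
    stimulus window; the initial condition is the I=0 steady state of the
    temperature-scaled model.  ``method`` selects the default fixed-step
    RK4 integrator ("rk4") or an adaptive stiff oracle ("lsoda", "radau",
    "bdf") evaluated on the same output grid.
    """
    if protocol is None:
        protocol = StimulusProtocol()
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if method == "rk4" and dt > 0.01 + 1e-12:
        raise ValueError("fixed-step integration requires dt <= 0.01 ms")

    scaled, rmult = temperature_scale(params, q10s, delta_t)
    rm, rh, rn, ra, rb = (rmult[g] for g in GATE_NAMES)
    v0, gates0 = resting_state(scaled)
    y0 = np.array([v0, gates0["m"], gates0["h"], gates0["n"], gates0["a"], gates0["b"]])

    n_steps = int(round(protocol.total_ms / dt))
    t = np.arange(n_steps + 1) * dt
    i_c = np.where((t >= protocol.t_start) & (t < protocol.t_stop), amplitude, 0.0)

    if method == "rk4":
        from ._engine import rk4_trace

        Y = rk4_trace(
            y0,
            np.array(scaled.conductances),
            np.array(scaled.reversals),
            scaled.C_m,
            np.array([rm, rh, rn, ra, rb]),
            amplitude,
            protocol.t_start,
            protocol.t_stop,
            dt,
            n_steps,
        )
        if not np.all(np.isfinite(Y[-1])):
            bad = np.where(~np.isfinite(Y).all(axis=1))[0]
            raise SimulationBlowupError(float(t[bad[0]]))
    else:
        def rhs(tt, y):
            ic = amplitude if protocol.t_start <= tt < protocol.t_stop else 0.0
            return _derivatives(*y, ic, scaled, rm, rh, rn, ra, rb)

        sol = solve_ivp(
            rhs,
            (0.0, t[-1]),
            y0,
            method={"lsoda": "LSODA", "radau": "Radau", "bdf": "BDF"}[method],
            t_eval=t,
            max_step=1.0,
            rtol=1e-8,
            atol=1e-8,
        )
        if not sol.success:
            raise SimulationBlowupError(float(sol.t[-1]) if len(sol.t) else 0.0)
        Y = sol.y.T

    V = Y[:, 0]
    gates = {g: Y[:, i + 1] for i, g in enumerate(GATE_NAMES)}
    return SimulationTrace(
        t=t,
        V=V,
        gates=gates,
        I_Na=scaled.g_Na * gates["m"] ** 3 * gates["h"] * (V - scaled.E_Na),
        I_K=scaled.g_K * gates["n"] ** 4 * (V - scaled.E_K),
        I_A=scaled.g_A * gates["a"] ** 3 * gates["b"] * (V - scaled.E_A),
        I_L=scaled.g_L * (V - scaled.E_L),
        I_C=i_c,
        temperature=params.T0 + delta_t,
        dt=dt,
    )


# ---------------------------------------------------------------------------
# spike detection and f-I curves
# ---------------------------------------------------------------------------

def detect_spikes(
    t: np.ndarray,
    V: np.ndarray,
    threshold: float = -30.0,
    lockout_ms: float = 1.0,
) -> np.ndarray:
    """Times of strict upward threshold crossings (V[i] < thr <= V[i+1]).

    Crossing times are linearly interpolated between samples; crossings
    closer than ``lockout_ms`` to the previous accepted one are discarded
    (guard against double counting on noisy traces).
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    idx = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold))
    # a trace that touches the threshold exactly but never exceeds it does
    # not count as a crossing
    keep = []
    for i in idx:
        j = i + 1
        while j < V.size and V[j] >= threshold:
            if V[j] > threshold:
                keep.append(i)
                break
            j += 1
    idx = np.asarray(keep, dtype=int)
    if idx.size == 0:
        return np.empty(0)
    frac = np.where(
        V[idx + 1] > V[idx],
        (threshold - V[idx]) / (V[idx + 1] - V[idx]),
        0.0,
    )
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    kept = [times[0]]
    for ts in times[1:]:
        if ts - kept[-1] >= lockout_ms:
            kept.append(ts)
    return np.asarray(kept)


def compute_fi_curve(
    params: NeuronParameters,
    q10s: Q10Set,
    temperature: float,
    protocol: StimulusProtocol | None = None,
    dt: float = 0.01,
    method: str = "rk4",
    fit: bool = True,
) -> FICurve:
    """f-I curve at one temperature: rate = spikes in the stimulus window
    divided by the stimulus duration, for every protocol amplitude."""
    if protocol is None:
        protocol = StimulusProtocol()
    if len(protocol.amplitudes) < 2:
        raise ValueError("protocol must define at least 2 amplitudes")
    rates = np.empty(len(protocol.amplitudes))
    for i, amp in enumerate(protocol.amplitudes):
        try:
            trace = simulate_voltage(
                params, q10s, temperature - params.T0, amp, protocol, dt, method
            )
        except SimulationBlowupError as exc:
            raise SimulationBlowupError(exc.time_ms) from RuntimeError(
                f"simulation failed at amplitude {amp}"
            )
        spikes = detect_spikes(trace.t, trace.V)
        in_window = (spikes >= protocol.t_start) & (spikes < protocol.t_stop)
        rates[i] = np.count_nonzero(in_window) / (protocol.stim_ms / 1000.0)
    curve = FICurve(temperature, np.asarray(protocol.amplitudes), rates)
    if fit:
        try:
            curve.A, curve.I0, curve.r_squared = fit_sqrt(curve.currents, curve.rates)
        except InsufficientDataError:
            pass
    return curve


def sqrt_model(I: np.ndarray, A: float, I0: float) -> np.ndarray:
    """Type I rate model: zero below threshold, A*sqrt(I - I0) above."""
    return A * np.sqrt(np.maximum(np.asarray(I, dtype=float) - I0, 0.0))


def fit_sqrt(
    currents: np.ndarray, rates: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares fit of ``A*sqrt(I - I0)`` to the suprathreshold samples.

    Zero-rate samples are excluded from the residual.  ``I0`` is bounded
    above by the smallest spiking amplitude; initialization follows the
    midpoint-threshold heuristic.  Returns ``(A, I0, R^2)`` with R^2
    computed over the fitted samples.
    """
    currents = np.asarray(currents, dtype=float)
    rates = np.asarray(rates, dtype=float)
    order = np.argsort(currents)
    currents, rates = currents[order], rates[order]
    pos = rates > 0
    if np.count_nonzero(pos) < 2:
        raise InsufficientDataError("insufficient suprathreshold points")
    i_first = currents[pos][0]
    sub = currents[~pos]
    below = sub[sub < i_first]
    i0_init = 0.5 * (below.max() + i_first) if below.size else i_first - 0.025
    a_init = rates[pos][-1] / max(math.sqrt(currents[pos][-1] - i0_init), 1e-9)

    x, y = currents[pos], rates[pos]
    i0_hi = i_first - 1e-9

    def resid(p):
        return sqrt_model(x, p[0], p[1]) - y

    sol = least_squares(
        resid,
        x0=[max(a_init, 1e-6), min(i0_init, i0_hi - 1e-9)],
        bounds=([1e-12, -np.inf], [np.inf, i0_hi]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    A, I0 = float(sol.x[0]), float(sol.x[1])
    pred = sqrt_model(x, A, I0)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return A, I0, r2
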