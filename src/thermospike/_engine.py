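"""Numba kernels for fixed-step RK4 integration of the 6-state model.

Two entry points: ``rk4_trace`` stores the full trajectory for one
simulation (used by :func:`thermospike.model.simulate_voltage`), while
``batch_fi`` runs many scaled models over a set of step-current
amplitudes without storing traces, returning only the observables the
sweep needs (spike counts and sodium/potassium load integrals).

Both paths share one derivative routine so a sweep record and a direct
single-model simulation are bit-identical.  Voltage-dependent gating
rates are evaluated from a dense lookup table (0.01 mV grid, linear
interpolation; relative error < 1e-6, far below the RK4 discretization
error at dt = 0.01 ms) — this is what makes the 4^9 sweep tractable.

The injected current is piecewise constant per integration step, with
the window edges aligned to the step grid (dt divides the protocol
windows), so the step stimulus is represented exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

_EPS = 1e-6  # series window at the removable singularities (mV)

_V_LO = -150.0
_V_HI = 80.0
_DV = 0.01


def _build_rate_table() -> np.ndarray:
    """Columns: am, bm, ah, bh, an, bn, a_inf, tau_a, b_inf, tau_b."""
    V = np.arange(_V_LO, _V_HI + _DV / 2, _DV)
    u = V + 29.7
    safe = np.where(np.abs(u) < _EPS, 1.0, u)
    am = np.where(np.abs(u) < _EPS, 3.8 + 0.19 * u,
                  0.38 * safe / (1.0 - np.exp(-0.1 * safe)))
    bm = 15.2 * np.exp(-0.0556 * (V + 54.7))
    ah = 0.266 * np.exp(-0.05 * (V + 48.0))
    bh = 3.8 / (1.0 + np.exp(-0.1 * (V + 18.0)))
    u = V + 45.7
    safe = np.where(np.abs(u) < _EPS, 1.0, u)
    an = np.where(np.abs(u) < _EPS, 0.2 + 0.01 * u,
                  0.02 * safe / (1.0 - np.exp(-0.1 * safe)))
    bn = 0.25 * np.exp(-0.0125 * (V + 55.7))
    # clamped at 1: the printed expression marginally exceeds 1 near +40 mV
    a_inf = np.minimum(
        (0.0761 * np.exp(0.0314 * (V + 94.22))
         / (1.0 + np.exp(0.0346 * (V + 1.17)))) ** (1.0 / 3.0),
        1.0,
    )
    tau_a = 0.3632 + 1.158 / (1.0 + np.exp(0.0497 * (V + 55.96)))
    b_inf = (1.0 / (1.0 + np.exp(0.0688 * (V + 53.3)))) ** 4
    tau_b = 1.24 + 2.678 / (1.0 + np.exp(0.0624 * (V + 50.0)))
    return np.ascontiguousarray(
        np.stack([am, bm, ah, bh, an, bn, a_inf, tau_a, b_inf, tau_b], axis=1)
    )


_TAB = _build_rate_table()
_NV = _TAB.shape[0]
_INV_DV = 1.0 / _DV


@njit(cache=True, fastmath=True, inline="always")
def _deriv(V, m, h, n, a, b, ic, gL, gNa, gK, gA, EL, ENa, EK, EA, Cm,
           rm, rh, rn, ra, rb, tab):
    x = (V - _V_LO) * _INV_DV
    i = int(x)
    if i < 0:
        i = 0
    elif i > _NV - 2:
        i = _NV - 2
    f = x - i
    am = tab[i, 0] + f * (tab[i + 1, 0] - tab[i, 0])
    bm = tab[i, 1] + f * (tab[i + 1, 1] - tab[i, 1])
    ah = tab[i, 2] + f * (tab[i + 1, 2] - tab[i, 2])
    bh = tab[i, 3] + f * (tab[i + 1, 3] - tab[i, 3])
    an = tab[i, 4] + f * (tab[i + 1, 4] - tab[i, 4])
    bn = tab[i, 5] + f * (tab[i + 1, 5] - tab[i, 5])
    a_inf = tab[i, 6] + f * (tab[i + 1, 6] - tab[i, 6])
    tau_a = tab[i, 7] + f * (tab[i + 1, 7] - tab[i, 7])
    b_inf = tab[i, 8] + f * (tab[i + 1, 8] - tab[i, 8])
    tau_b = tab[i, 9] + f * (tab[i + 1, 9] - tab[i, 9])

    i_l = gL * (V - EL)
    i_na = gNa * m * m * m * h * (V - ENa)
    i_k = gK * n * n * n * n * (V - EK)
    i_a = gA * a * a * a * b * (V - EA)
    dV = 1000.0 / Cm * (ic - i_l - i_na - i_k - i_a)
    dm = rm * (am * (1.0 - m) - bm * m)
    dh = rh * (ah * (1.0 - h) - bh * h)
    dn = rn * (an * (1.0 - n) - bn * n)
    da = ra * (a_inf - a) / tau_a
    db = rb * (b_inf - b) / tau_b
    return dV, dm, dh, dn, da, db


@njit(cache=True, fastmath=True)
def _rk4_trace(y0, g, E, Cm, r, amp, t_start, t_stop, dt, n_steps, tab):
    gL, gNa, gK, gA = g[0], g[1], g[2], g[3]
    EL, ENa, EK, EA = E[0], E[1], E[2], E[3]
    rm, rh, rn, ra, rb = r[0], r[1], r[2], r[3], r[4]
    out = np.empty((n_steps + 1, 6))
    V, m, h, n, a, b = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5]
    out[0, 0], out[0, 1], out[0, 2] = V, m, h
    out[0, 3], out[0, 4], out[0, 5] = n, a, b
    for k in range(n_steps):
        t = k * dt
        ic = amp if (t >= t_start - 1e-9 and t < t_stop - 1e-9) else 0.0
        d1 = _deriv(V, m, h, n, a, b, ic, gL, gNa, gK, gA, EL, ENa, EK, EA, Cm,
                    rm, rh, rn, ra, rb, tab)
        d2 = _deriv(V + 0.5 * dt * d1[0], m + 0.5 * dt * d1[1],
                    h + 0.5 * dt * d1[2], n + 0.5 * dt * d1[3],
                    a + 0.5 * dt * d1[4], b + 0.5 * dt * d1[5], ic,
                    gL, gNa, gK, gA, EL, ENa, EK, EA, Cm, rm, rh, rn, ra, rb, tab)
        d3 = _deriv(V + 0.5 * dt * d2[0], m + 0.5 * dt * d2[1],
                    h + 0.5 * dt * d2[2], n + 0.5 * dt * d2[3],
                    a + 0.5 * dt * d2[4], b + 0.5 * dt * d2[5], ic,
                    gL, gNa, gK, gA, EL, ENa, EK, EA, Cm, rm, rh, rn, ra, rb, tab)
        d4 = _deriv(V + dt * d3[0], m + dt * d3[1], h + dt * d3[2],
                    n + dt * d3[3], a + dt * d3[4], b + dt * d3[5], ic,
                    gL, gNa, gK, gA, EL, ENa, EK, EA, Cm, rm, rh, rn, ra, rb, tab)
        V += dt / 6.0 * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
        m += dt / 6.0 * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
        h += dt / 6.0 * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2])
        n += dt / 6.0 * (d1[3] + 2.0 * d2[3] + 2.0 * d3[3] + d4[3])
        a += dt / 6.0 * (d1[4] + 2.0 * d2[4] + 2.0 * d3[4] + d4[4])
        b += dt / 6.0 * (d1[5] + 2.0 * d2[5] + 2.0 * d3[5] + d4[5])
        out[k + 1, 0], out[k + 1, 1], out[k + 1, 2] = V, m, h
        out[k + 1, 3], out[k + 1, 4], out[k + 1, 5] = n, a, b
    return out


def rk4_trace(y0, g, E, Cm, r, amp, t_start, t_stop, dt, n_steps):
    """RK4 integration storing the full 6-state trajectory."""
    return _rk4_trace(y0, g, E, Cm, r, amp, t_start, t_stop, dt, n_steps, _TAB)


@njit(cache=True, fastmath=True)
def _fi_one(y0, gL, gNa, gK, gA, EL, ENa, EK, EA, Cm, rm, rh, rn, ra, rb,
            amps, t_start, t_stop, t_load_end, total_ms, dt,
            threshold, lockout, tab, counts, loads_na, loads_k, counts_load):
    """One model, all amplitudes: spike counts and current-load integrals.

    Per amplitude, fills: spikes in [t_start, t_stop); trapezoidal
    integral of |I_Na| and |I_K|+|I_A| over [t_start, t_load_end]; spike
    count in that same load window.
    """
    n_steps = int(round(total_ms / dt))
    for j in range(amps.shape[0]):
        amp = amps[j]
        V, m, h, n, a, b = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5]
        n_stim = 0
        n_load = 0
        last_spike = -1e9
        load_na = 0.0
        load_k = 0.0
        ina_prev = np.abs(gNa * m * m * m * h * (V - ENa))
        ik_prev = (np.abs(gK * n * n * n * n * (V - EK))
                   + np.abs(gA * a * a * a * b * (V - EA)))
        ok = True
        for k in range(n_steps):
            t = k * dt
            ic = amp if (t >= t_start - 1e-9 and t < t_stop - 1e-9) else 0.0
            V_prev = V
            d1 = _deriv(V, m, h, n, a, b, ic, gL, gNa, gK, gA, EL, ENa, EK, EA,
                        Cm, rm, rh, rn, ra, rb, tab)
            d2 = _deriv(V + 0.5 * dt * d1[0], m + 0.5 * dt * d1[1],
                        h + 0.5 * dt * d1[2], n + 0.5 * dt * d1[3],
                        a + 0.5 * dt * d1[4], b + 0.5 * dt * d1[5], ic,
                        gL, gNa, gK, gA, EL, ENa, EK, EA, Cm,
                        rm, rh, rn, ra, rb, tab)
            d3 = _deriv(V + 0.5 * dt * d2[0], m + 0.5 * dt * d2[1],
                        h + 0.5 * dt * d2[2], n + 0.5 * dt * d2[3],
                        a + 0.5 * dt * d2[4], b + 0.5 * dt * d2[5], ic,
                        gL, gNa, gK, gA, EL, ENa, EK, EA, Cm,
                        rm, rh, rn, ra, rb, tab)
            d4 = _deriv(V + dt * d3[0], m + dt * d3[1], h + dt * d3[2],
                        n + dt * d3[3], a + dt * d3[4], b + dt * d3[5], ic,
                        gL, gNa, gK, gA, EL, ENa, EK, EA, Cm,
                        rm, rh, rn, ra, rb, tab)
            V += dt / 6.0 * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
            m += dt / 6.0 * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
            h += dt / 6.0 * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2])
            n += dt / 6.0 * (d1[3] + 2.0 * d2[3] + 2.0 * d3[3] + d4[3])
            a += dt / 6.0 * (d1[4] + 2.0 * d2[4] + 2.0 * d3[4] + d4[4])
            b += dt / 6.0 * (d1[5] + 2.0 * d2[5] + 2.0 * d3[5] + d4[5])
            if not np.isfinite(V):
                ok = False
                break
            t_new = t + dt
            # load integrals (window edges aligned to the step grid)
            ina_new = np.abs(gNa * m * m * m * h * (V - ENa))
            ik_new = (np.abs(gK * n * n * n * n * (V - EK))
                      + np.abs(gA * a * a * a * b * (V - EA)))
            if t >= t_start - 1e-9 and t_new <= t_load_end + 1e-9:
                load_na += 0.5 * (ina_prev + ina_new) * dt
                load_k += 0.5 * (ik_prev + ik_new) * dt
            ina_prev = ina_new
            ik_prev = ik_new
            # strict upward crossing with interpolated time + lockout
            if V_prev < threshold and V >= threshold:
                ts = t + dt * (threshold - V_prev) / (V - V_prev)
                if ts - last_spike >= lockout:
                    last_spike = ts
                    if t_start <= ts < t_stop:
                        n_stim += 1
                    if t_start <= ts <= t_load_end:
                        n_load += 1
        if ok:
            counts[j] = n_stim
            loads_na[j] = load_na
            loads_k[j] = load_k
            counts_load[j] = n_load
        else:
            counts[j] = -1
            loads_na[j] = np.nan
            loads_k[j] = np.nan
            counts_load[j] = -1


@njit(cache=True, fastmath=True, parallel=True)
def _batch_fi(y0s, gs, E, Cm, rs, amps, t_start, t_stop, t_load_end,
              total_ms, dt, threshold, lockout, tab):
    n_models = gs.shape[0]
    n_amps = amps.shape[0]
    counts = np.empty((n_models, n_amps), dtype=np.int64)
    loads_na = np.empty((n_models, n_amps))
    loads_k = np.empty((n_models, n_amps))
    counts_load = np.empty((n_models, n_amps), dtype=np.int64)
    for i in prange(n_models):
        _fi_one(y0s[i], gs[i, 0], gs[i, 1], gs[i, 2], gs[i, 3],
                E[0], E[1], E[2], E[3], Cm,
                rs[i, 0], rs[i, 1], rs[i, 2], rs[i, 3], rs[i, 4],
                amps, t_start, t_stop, t_load_end, total_ms, dt,
                threshold, lockout, tab,
                counts[i], loads_na[i], loads_k[i], counts_load[i])
    return counts, loads_na, loads_k, counts_load


def batch_fi(y0s, gs, E, Cm, rs, amps, t_start, t_stop, t_load_end,
             total_ms, dt, threshold, lockout):
    """All models x all amplitudes.

    Parameters are the already temperature-scaled per-model values:
    ``y0s (n, 6)`` initial states, ``gs (n, 4)`` conductances,
    ``E (4,)`` shared reversal potentials, ``rs (n, 5)`` gate-rate
    multipliers.  Returns ``(counts, loads_na, loads_k, counts_load)``
    with shape ``(n, n_amps)``; a count of -1 flags integration failure.
    """
    return _batch_fi(y0s, gs, E, Cm, rs, amps, t_start, t_stop, t_load_end,
                     total_ms, dt, threshold, lockout, _TAB)
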