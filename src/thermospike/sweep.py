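"""Q10 grid sweeps: RMSD robustness metric, full factorial exploration,
perturbed reference models and genetic-algorithm RMSD minimization.

The nine temperature-dependence parameters are enumerated in the fixed
order ``(g_L, g_Na, g_K, g_A, m, h, n, a, b)`` with lexicographic index
(last parameter fastest), so record indices are stable across runs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._engine import batch_fi
from .model import (
    CONDUCTANCE_NAMES,
    GATE_NAMES,
    InsufficientDataError,
    NeuronParameters,
    Q10Set,
    StimulusProtocol,
    fit_sqrt,
)

__all__ = [
    "PARAM_ORDER",
    "Q10Grid",
    "SweepTable",
    "q10_of",
    "rmsd",
    "run_sweep",
    "perturbed_reference_models",
    "minimize_rmsd",
    "rmsd_objective",
    "hot_observables",
]

#: fixed parameter ordering for grid enumeration and result columns
PARAM_ORDER = CONDUCTANCE_NAMES + GATE_NAMES


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def q10_of(x_cold: float, x_hot: float, delta_t: float) -> float:
    """Temperature coefficient ``(x_hot / x_cold) ** (10 / delta_t)``."""
    if delta_t == 0:
        raise ValueError("delta_t must be nonzero")
    if x_cold <= 0 or x_hot <= 0:
        raise ValueError("q10_of requires positive observables")
    return (x_hot / x_cold) ** (10.0 / delta_t)


def rmsd(f_cold: np.ndarray, f_hot: np.ndarray) -> float:
    """Root-mean-squared rate difference normalized by the cold mean rate.

    All entries enter the sums, including zero-rate (subthreshold) ones.
    """
    f_cold = np.asarray(f_cold, dtype=float)
    f_hot = np.asarray(f_hot, dtype=float)
    if f_cold.shape != f_hot.shape or f_cold.size == 0:
        raise ValueError("rate vectors must be nonempty and of equal length")
    denom = f_cold.mean()
    if denom <= 0:
        raise ValueError("degenerate normalization: mean cold rate is zero")
    return float(np.sqrt(np.mean((f_cold - f_hot) ** 2)) / denom)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Q10Grid:
    """Full factorial grid over the nine Q10 parameters.

    ``values`` holds one sorted level list per parameter, in
    :data:`PARAM_ORDER`.  Enumeration is lexicographic with the last
    parameter varying fastest (C order).
    """

    values: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.values) != 9:
            raise ValueError("grid needs one level list per parameter (9)")
        object.__setattr__(
            self, "values", tuple(tuple(float(v) for v in row) for row in self.values)
        )

    @classmethod
    def default(cls, steps: int = 4) -> "Q10Grid":
        """Evenly spaced levels: conductances in [1.2, 2.0], rates in [2.0, 4.0]."""
        if steps < 1:
            raise ValueError("steps must be >= 1")
        if steps == 1:
            cond: tuple[float, ...] = (1.2,)
            gate: tuple[float, ...] = (2.0,)
        else:
            cond = tuple(np.linspace(1.2, 2.0, steps))
            gate = tuple(np.linspace(2.0, 4.0, steps))
        return cls(tuple([cond] * 4 + [gate] * 5))

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.values)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def coords(self, index: int) -> tuple[int, ...]:
        if not 0 <= index < self.size:
            raise IndexError("grid index out of range")
        return tuple(int(c) for c in np.unravel_index(index, self.shape))

    def index(self, coords: Sequence[int]) -> int:
        return int(np.ravel_multi_index(tuple(coords), self.shape))

    def q10set(self, index: int) -> Q10Set:
        c = self.coords(index)
        return Q10Set(*(self.values[k][c[k]] for k in range(9)))

    def q10_matrix(self, indices: np.ndarray | None = None) -> np.ndarray:
        """(n, 9) array of Q10 values for ``indices`` (default: all points)."""
        if indices is None:
            indices = np.arange(self.size)
        indices = np.asarray(indices, dtype=np.int64)
        coords = np.array(np.unravel_index(indices, self.shape)).T
        out = np.empty((len(indices), 9))
        for k in range(9):
            out[:, k] = np.asarray(self.values[k])[coords[:, k]]
        return out

    def index_of_q10set(self, q10s: Q10Set) -> int:
        coords = []
        arr = q10s.as_array()
        for k in range(9):
            levels = np.asarray(self.values[k])
            j = int(np.argmin(np.abs(levels - arr[k])))
            if abs(levels[j] - arr[k]) > 1e-9:
                raise ValueError("Q10Set is not a grid point")
            coords.append(j)
        return self.index(coords)


# ---------------------------------------------------------------------------
# scaled-model preparation shared by sweep / GA / acceptance
# ---------------------------------------------------------------------------

def _resting_fast(gL, gNa, gK, gA, EL, ENa, EK, EA):
    """Scalar resting-state solve (math-only rate evaluation, brentq)."""
    from scipy.optimize import brentq

    def xinf(V):
        u = V + 29.7
        am = 0.38 * u / (1 - math.exp(-0.1 * u)) if abs(u) > 1e-6 else 3.8
        bm = 15.2 * math.exp(-0.0556 * (V + 54.7))
        ah = 0.266 * math.exp(-0.05 * (V + 48.0))
        bh = 3.8 / (1 + math.exp(-0.1 * (V + 18.0)))
        u = V + 45.7
        an = 0.02 * u / (1 - math.exp(-0.1 * u)) if abs(u) > 1e-6 else 0.2
        bn = 0.25 * math.exp(-0.0125 * (V + 55.7))
        ainf = min((0.0761 * math.exp(0.0314 * (V + 94.22))
                    / (1 + math.exp(0.0346 * (V + 1.17)))) ** (1.0 / 3.0), 1.0)
        binf = (1 / (1 + math.exp(0.0688 * (V + 53.3)))) ** 4
        return am / (am + bm), ah / (ah + bh), an / (an + bn), ainf, binf

    def net(V):
        m, h, n, a, b = xinf(V)
        return (gL * (EL - V) + gNa * m**3 * h * (ENa - V)
                + gK * n**4 * (EK - V) + gA * a**3 * b * (EA - V))

    lo = min(EL, ENa, EK, EA)
    hi = max(EL, ENa, EK, EA)
    vr = brentq(net, lo, hi, xtol=1e-9)
    m, h, n, a, b = xinf(vr)
    return vr, m, h, n, a, b


def scaled_batch_inputs(
    params: NeuronParameters,
    q10_matrix: np.ndarray,
    delta_t: float,
    _rest_cache: dict | None = None,
):
    """Per-model engine inputs (initial states, conductances, reversals,
    rate multipliers) for ``q10_matrix`` of shape (n, 9) at ``delta_t``.

    Resting states depend only on the four conductance factors, so they
    are solved once per distinct conductance combination.
    """
    q10_matrix = np.atleast_2d(np.asarray(q10_matrix, dtype=float))
    n = q10_matrix.shape[0]
    fac = q10_matrix ** (delta_t / 10.0)
    gs = np.asarray(params.conductances) * fac[:, :4]
    e_fac = 1.0 + delta_t / (params.T0 + 273.15)
    E = np.asarray(params.reversals) * e_fac
    rs = np.ascontiguousarray(fac[:, 4:])
    y0s = np.empty((n, 6))
    cache = _rest_cache if _rest_cache is not None else {}
    for i in range(n):
        key = tuple(np.round(gs[i], 12))
        if key not in cache:
            cache[key] = _resting_fast(*gs[i], *E)
        y0s[i] = cache[key]
    return y0s, np.ascontiguousarray(gs), E, rs


def hot_observables(
    params: NeuronParameters,
    q10_matrix: np.ndarray,
    delta_t: float,
    protocol: StimulusProtocol,
    dt: float = 0.01,
    load_tail_ms: float = 20.0,
    _rest_cache: dict | None = None,
):
    """Engine pass over models: firing rates (Hz), Na and K load integrals
    over [stimulus onset, offset + ``load_tail_ms``], and the spike counts
    inside the load window.  Rows with failed integrations have rate NaN.
    """
    y0s, gs, E, rs = scaled_batch_inputs(params, q10_matrix, delta_t, _rest_cache)
    amps = np.asarray(protocol.amplitudes, dtype=float)
    t_load_end = min(protocol.t_stop + load_tail_ms, protocol.total_ms)
    counts, loads_na, loads_k, counts_load = batch_fi(
        y0s, gs, E, params.C_m, rs, amps,
        protocol.t_start, protocol.t_stop, t_load_end,
        protocol.total_ms, dt, -30.0, 1.0,
    )
    rates = counts / (protocol.stim_ms / 1000.0)
    rates[counts < 0] = np.nan
    return rates, loads_na, loads_k, counts_load


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepTable:
    """One record per grid point plus the provenance needed to rerun it."""

    table: pd.DataFrame
    grid: Q10Grid
    config: dict

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, directory: str | Path, name: str = "sweep") -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{name}.csv"
        self.table.to_csv(csv_path, index=False)
        sidecar = dict(self.config, config_hash=self.config_hash)
        (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=2))
        return csv_path

    @classmethod
    def load(cls, directory: str | Path, name: str = "sweep") -> "SweepTable":
        directory = Path(directory)
        table = pd.read_csv(directory / f"{name}.csv",
                            float_precision="round_trip")
        config = json.loads((directory / f"{name}.json").read_text())
        config.pop("config_hash", None)
        grid = Q10Grid(tuple(tuple(v) for v in config["grid"]))
        return cls(table, grid, config)


def _fit_row(currents: np.ndarray, rates: np.ndarray):
    try:
        return fit_sqrt(currents, rates)
    except InsufficientDataError:
        return (np.nan, np.nan, np.nan)


def _mean_ratio_q10(
    loads_cold, counts_cold, loads_hot, counts_hot, delta_t, per_amplitude=True
):
    """Q10 of load-per-spike averaged over amplitudes spiking at both
    temperatures.  ``per_amplitude=False`` switches to the ratio of mean
    loads instead of the mean of per-amplitude ratios."""
    ok = (counts_cold > 0) & (counts_hot > 0)
    if not np.any(ok):
        return np.nan
    lc = loads_cold[ok] / counts_cold[ok]
    lh = loads_hot[ok] / counts_hot[ok]
    if per_amplitude:
        return float(np.mean((lh / lc) ** (10.0 / delta_t)))
    return float((lh.mean() / lc.mean()) ** (10.0 / delta_t))


def run_sweep(
    grid: Q10Grid,
    params: NeuronParameters | None = None,
    protocol: StimulusProtocol | None = None,
    t_cold: float = 18.0,
    t_hot: float = 28.0,
    dt: float = 0.01,
    indices: np.ndarray | None = None,
    chunk_size: int = 8192,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> SweepTable:
    """Evaluate every grid point (or a subset ``indices``) at two
    temperatures.

    Produces per-model RMSD, square-root fit parameters and their Q10s,
    spiking-cost Q10s (Na and K referenced), resting-potential costs and
    their Q10s, and the Fisher-information Q10.  When ``t_cold`` equals
    the reference temperature the cold observables are shared by all
    models and computed once.  Results are cached by a content hash of
    the configuration when ``cache_dir`` is given.
    """
    params = params or NeuronParameters()
    protocol = protocol or StimulusProtocol()
    config = {
        "grid": [list(v) for v in grid.values],
        "params": {k: getattr(params, k) for k in (
            "g_L", "g_Na", "g_K", "g_A", "E_L", "E_Na", "E_K", "E_A", "C_m", "T0")},
        "protocol": {
            "pre_ms": protocol.pre_ms, "stim_ms": protocol.stim_ms,
            "post_ms": protocol.post_ms, "amplitudes": list(protocol.amplitudes)},
        "t_cold": t_cold, "t_hot": t_hot, "dt": dt,
        "indices": None if indices is None else [int(i) for i in indices],
    }
    cached = None
    if cache_dir is not None:
        payload = json.dumps(config, sort_keys=True).encode()
        h = hashlib.sha256(payload).hexdigest()[:16]
        cached = Path(cache_dir) / f"sweep-{h}.csv"
        if cached.exists():
            return SweepTable(
                pd.read_csv(cached, float_precision="round_trip"),
                grid, config)

    if indices is None:
        indices = np.arange(grid.size)
    indices = np.asarray(indices, dtype=np.int64)
    delta_cold = t_cold - params.T0
    delta_hot = t_hot - params.T0
    delta_t = t_hot - t_cold
    amps = np.asarray(protocol.amplitudes)

    cold_shared = abs(delta_cold) < 1e-12
    rest_cache_cold: dict = {}
    rest_cache_hot: dict = {}
    if cold_shared:
        c_rates, c_ln, c_lk, c_nl = hot_observables(
            params, np.ones((1, 9)), 0.0, protocol, dt, _rest_cache=rest_cache_cold)
        cold_fit_shared = _fit_row(amps, c_rates[0])

    from .energetics import resting_costs_for_conductance_factors

    rows = []
    for lo in range(0, len(indices), chunk_size):
        sl = indices[lo:lo + chunk_size]
        q10m = grid.q10_matrix(sl)
        h_rates, h_ln, h_lk, h_nl = hot_observables(
            params, q10m, delta_hot, protocol, dt, _rest_cache=rest_cache_hot)
        if cold_shared:
            rates_c = np.broadcast_to(c_rates[0], h_rates.shape)
            ln_c = np.broadcast_to(c_ln[0], h_rates.shape)
            lk_c = np.broadcast_to(c_lk[0], h_rates.shape)
            nl_c = np.broadcast_to(c_nl[0], h_rates.shape)
        else:
            rates_c, ln_c, lk_c, nl_c = hot_observables(
                params, q10m, delta_cold, protocol, dt, _rest_cache=rest_cache_cold)
        for j, gi in enumerate(sl):
            rec = {"index": int(gi)}
            for k, name in enumerate(PARAM_ORDER):
                rec[f"q10_{name}"] = q10m[j, k]
            fc, fh = rates_c[j], h_rates[j]
            failed = bool(np.any(np.isnan(fc)) or np.any(np.isnan(fh)))
            rec["failed"] = failed
            if failed or fc.mean() <= 0:
                rec["rmsd"] = np.nan
            else:
                rec["rmsd"] = rmsd(fc, fh)
            if cold_shared:
                a_c, i0_c, r2_c = cold_fit_shared
            else:
                a_c, i0_c, r2_c = _fit_row(amps, fc)
            a_h, i0_h, r2_h = _fit_row(amps, fh)
            rec.update(A_cold=a_c, I0_cold=i0_c, r2_cold=r2_c,
                       A_hot=a_h, I0_hot=i0_h, r2_hot=r2_h)
            rec["q10_A"] = (
                (a_h / a_c) ** (10.0 / delta_t)
                if a_c > 0 and a_h > 0 else np.nan)
            rec["q10_I0"] = (
                (i0_h / i0_c) ** (10.0 / delta_t)
                if i0_c > 0 and i0_h > 0 else np.nan)
            rec["q10_fisher"] = rec["q10_A"] ** 4 if np.isfinite(rec["q10_A"]) else np.nan
            rec["q10_spiking_cost"] = _mean_ratio_q10(
                ln_c[j], nl_c[j], h_ln[j], h_nl[j], delta_t)
            rec["q10_spiking_cost_k"] = _mean_ratio_q10(
                lk_c[j], nl_c[j], h_lk[j], h_nl[j], delta_t)
            rest = resting_costs_for_conductance_factors(
                params, q10m[j, :4], delta_cold, delta_hot)
            rec.update(rest)
            rows.append(rec)
        if progress:
            print(f"sweep: {min(lo + chunk_size, len(indices))}/{len(indices)}")

    table = pd.DataFrame(rows)
    result = SweepTable(table, grid, config)
    if cached is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(cached, index=False)
    return result


# ---------------------------------------------------------------------------
# perturbed reference models
# ---------------------------------------------------------------------------

def perturbed_reference_models(
    params: NeuronParameters | None = None, factor: float = 0.2
) -> list[NeuronParameters]:
    """24 perturbations of the reference peak conductances.

    8 models with one conductance scaled by 1 +/- factor, plus all 16
    sign combinations applied to the four conductances jointly.  The
    unperturbed reference is not included.
    """
    params = params or NeuronParameters()
    if not 0 < factor < 1:
        raise ValueError("factor must be in (0, 1)")
    out = []
    for name in CONDUCTANCE_NAMES:
        for sign in (-1.0, 1.0):
            out.append(
                replace(params, **{name: getattr(params, name) * (1 + sign * factor)})
            )
    for pattern in range(16):
        kwargs = {}
        for k, name in enumerate(CONDUCTANCE_NAMES):
            sign = 1.0 if (pattern >> k) & 1 else -1.0
            kwargs[name] = getattr(params, name) * (1 + sign * factor)
        out.append(replace(params, **kwargs))
    return out


# ---------------------------------------------------------------------------
# RMSD objective and genetic algorithm
# ---------------------------------------------------------------------------

def rmsd_objective(
    params: NeuronParameters | None = None,
    protocol: StimulusProtocol | None = None,
    t_cold: float = 18.0,
    t_hot: float = 28.0,
    dt: float = 0.01,
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized RMSD objective over (n, 9) Q10 matrices."""
    params = params or NeuronParameters()
    protocol = protocol or StimulusProtocol()
    rest_cache: dict = {}
    cold, *_ = hot_observables(
        params, np.ones((1, 9)), t_cold - params.T0, protocol, dt)
    f_cold = cold[0]
    denom = f_cold.mean()

    def objective(q10_matrix: np.ndarray) -> np.ndarray:
        q10_matrix = np.atleast_2d(q10_matrix)
        hot, *_ = hot_observables(
            params, q10_matrix, t_hot - params.T0, protocol, dt,
            _rest_cache=rest_cache)
        return np.sqrt(np.mean((f_cold - hot) ** 2, axis=1)) / denom

    return objective


_DEFAULT_BOUNDS = tuple([Q10Set.CONDUCTANCE_RANGE] * 4 + [Q10Set.GATE_RANGE] * 5)


def minimize_rmsd(
    objective: Callable[[np.ndarray], np.ndarray] | None = None,
    bounds: Sequence[tuple[float, float]] = _DEFAULT_BOUNDS,
    seed: int = 0,
    population: int = 1000,
    generations: int = 150,
    bits: int = 8,
    mutation_rate: float | None = None,
    elite: int = 2,
):
    """Elitist generational GA with per-parameter binary encoding.

    Chromosomes hold ``bits`` bits per parameter, decoded linearly into
    ``bounds``.  Tournament selection (size 2), single-point crossover on
    the bit string, per-bit mutation, elitism.  Deterministic for a fixed
    seed.  Returns ``(best Q10Set, best objective value)`` (a plain array
    when the bounds are not the nine Q10 parameters).
    """
    bounds = tuple(bounds)
    if len(bounds) == 0:
        raise ValueError("bounds must be nonempty")
    if population <= 0 or generations <= 0:
        raise ValueError("population and generations must be positive")
    if objective is None:
        objective = rmsd_objective()
    n_par = len(bounds)
    n_bits = n_par * bits
    rng = np.random.default_rng(seed)
    if mutation_rate is None:
        mutation_rate = 1.0 / n_bits
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    scale = (hi - lo) / (2**bits - 1)
    weights = (2 ** np.arange(bits)[::-1]).astype(np.int64)

    def decode(pop_bits: np.ndarray) -> np.ndarray:
        ints = pop_bits.reshape(len(pop_bits), n_par, bits) @ weights
        return lo + ints * scale

    pop = rng.integers(0, 2, size=(population, n_bits), dtype=np.int64)
    fitness = np.asarray(objective(decode(pop)), dtype=float)
    fitness[~np.isfinite(fitness)] = np.inf

    for _ in range(generations):
        order = np.argsort(fitness, kind="stable")
        elite_bits = pop[order[:elite]].copy()
        i1 = rng.integers(0, population, size=population - elite)
        i2 = rng.integers(0, population, size=population - elite)
        parents = np.where((fitness[i1] <= fitness[i2])[:, None], pop[i1], pop[i2])
        children = parents.copy()
        for k in range(0, len(children) - 1, 2):
            cut = int(rng.integers(1, n_bits))
            children[k, cut:], children[k + 1, cut:] = (
                parents[k + 1, cut:].copy(), parents[k, cut:].copy())
        flip = rng.random(children.shape) < mutation_rate
        children = np.where(flip, 1 - children, children)
        pop = np.concatenate([elite_bits, children])
        fitness = np.asarray(objective(decode(pop)), dtype=float)
        fitness[~np.isfinite(fitness)] = np.inf

    best = int(np.argmin(fitness))
    values = decode(pop[best:best + 1])[0]
    if n_par == 9:
        return Q10Set.from_array(values), float(fitness[best])
    return values, float(fitness[best])
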