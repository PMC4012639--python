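"""Synthetic receptor-recording generator with known ground truth.

Emulates the shape of the study's intracellular dataset — 9 neurons,
8 sound intensities (32-88 dB SPL), 5 trials per intensity, 100 ms
stimuli at two temperatures — from sigmoidal rate-level curves whose
parameters carry configurable Q10s.  Trial spike counts follow a Poisson
or Gaussian noise model; spikes are placed on a two-plateau rate profile
so the early-phase (10-40 ms) to late-phase (70-100 ms) rate ratio is
exactly controllable; optional voltage-like traces render stylized
Gaussian action potentials with a temperature-dependent width at
half-maximum.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .transduction import SigmoidResponse

__all__ = [
    "GeneratorSpec",
    "SyntheticRecording",
    "generate_recordings",
    "ground_truth_table",
    "write_dataset",
    "load_dataset",
]

#: boundary between the early and the late rate plateau (ms)
_PLATEAU_SPLIT_MS = 55.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Configuration of one synthetic dataset."""

    n_neurons: int = 9
    temperatures: tuple[float, float] = (22.0, 28.5)
    intensities: tuple[float, ...] = (32, 40, 48, 56, 64, 72, 80, 88)
    trials: int = 5
    stim_ms: float = 100.0
    cold_responses: tuple[SigmoidResponse, ...] | None = None
    q10_sat: float = 1.4
    q10_i50: float = 1.0
    q10_width: float = 0.8
    noise: str = "gauss"            # "poisson" | "gauss" | "none"
    sigma_hz: float = 10.0          # Gaussian rate noise (Hz)
    early_late_ratio: float = 1.3   # early-plateau / late-plateau rate
    ap_width_ms: tuple[float, float] = (1.0, 0.66)   # at (cold, hot)
    ap_amplitude_mv: float = 80.0
    baseline_mv: float = -60.0
    render_traces: bool = False
    fs_hz: float = 20_000.0
    pre_ms: float = 20.0
    post_ms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if any(np.diff(self.intensities) <= 0):
            raise ValueError("intensities must be strictly increasing")
        if self.noise not in ("poisson", "gauss", "none"):
            raise ValueError("noise must be 'poisson', 'gauss' or 'none'")
        if self.noise == "gauss" and self.sigma_hz < 0:
            raise ValueError("Gaussian sigma must be >= 0")
        if min(self.ap_width_ms) <= 0:
            raise ValueError("AP widths must be > 0")
        if self.early_late_ratio <= 0:
            raise ValueError("early/late ratio must be > 0")

    def neuron_cold_responses(self) -> tuple[SigmoidResponse, ...]:
        """Per-neuron cold sigmoids; drawn deterministically from the seed
        when not given explicitly."""
        if self.cold_responses is not None:
            if len(self.cold_responses) != self.n_neurons:
                raise ValueError("one cold response per neuron required")
            return self.cold_responses
        rng = np.random.default_rng(self.seed)
        out = []
        for _ in range(self.n_neurons):
            out.append(SigmoidResponse(
                sat=float(rng.uniform(220.0, 320.0)),
                i50=float(rng.uniform(50.0, 62.0)),
                width=float(rng.uniform(3.0, 7.0)),
            ))
        return tuple(out)

    def response_at(self, neuron: int, temperature: float) -> SigmoidResponse:
        cold = self.neuron_cold_responses()[neuron]
        f = (temperature - self.temperatures[0]) / 10.0
        return SigmoidResponse(
            sat=cold.sat * self.q10_sat**f,
            i50=cold.i50 * self.q10_i50**f,
            width=cold.width * self.q10_width**f,
        )


@dataclass
class SyntheticRecording:
    """Generated dataset: tidy spike table, optional traces, ground truth."""

    spikes: pd.DataFrame
    traces: dict | None
    spec: GeneratorSpec

    @property
    def trace_time_ms(self) -> np.ndarray:
        n = int(round((self.spec.pre_ms + self.spec.stim_ms + self.spec.post_ms)
                      * self.spec.fs_hz / 1000.0))
        return np.arange(n) / self.spec.fs_hz * 1000.0 - self.spec.pre_ms


def _plateau_multipliers(ratio: float, stim_ms: float) -> tuple[float, float]:
    """Early/late plateau multipliers with unit time average."""
    w_early = _PLATEAU_SPLIT_MS / stim_ms
    w_late = 1.0 - w_early
    m_late = 1.0 / (w_early * ratio + w_late)
    return ratio * m_late, m_late


def _place_spikes(rng: np.random.Generator, count: int, stim_ms: float,
                  m_early: float, m_late: float) -> np.ndarray:
    if count == 0:
        return np.empty(0)
    p_early = m_early * _PLATEAU_SPLIT_MS / stim_ms
    u = rng.random(count)
    v = rng.random(count)
    early = u < p_early
    times = np.where(
        early,
        v * _PLATEAU_SPLIT_MS,
        _PLATEAU_SPLIT_MS + v * (stim_ms - _PLATEAU_SPLIT_MS),
    )
    return np.sort(times)


def _render_trace(spec: GeneratorSpec, spike_times: np.ndarray,
                  ap_width_ms: float) -> np.ndarray:
    total_ms = spec.pre_ms + spec.stim_ms + spec.post_ms
    n = int(round(total_ms * spec.fs_hz / 1000.0))
    t = np.arange(n) / spec.fs_hz * 1000.0 - spec.pre_ms
    V = np.full(n, spec.baseline_mv)
    sigma = ap_width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for ts in spike_times:
        V += spec.ap_amplitude_mv * np.exp(-0.5 * ((t - ts) / sigma) ** 2)
    return V


def generate_recordings(spec: GeneratorSpec) -> SyntheticRecording:
    """Generate the full dataset for ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed + 1)   # neuron params use spec.seed
    m_early, m_late = _plateau_multipliers(spec.early_late_ratio, spec.stim_ms)
    rows = []
    traces: dict = {} if spec.render_traces else None
    for neuron in range(spec.n_neurons):
        for t_idx, temperature in enumerate(spec.temperatures):
            rho = spec.response_at(neuron, temperature)
            ap_w = spec.ap_width_ms[t_idx]
            for intensity in spec.intensities:
                rate = float(rho(np.array(intensity)))
                mean_count = rate * spec.stim_ms / 1000.0
                for trial in range(spec.trials):
                    if spec.noise == "poisson":
                        count = int(rng.poisson(mean_count))
                    elif spec.noise == "gauss":
                        noisy = rate + rng.normal(0.0, spec.sigma_hz)
                        count = max(int(round(noisy * spec.stim_ms / 1000.0)), 0)
                    else:
                        count = int(round(mean_count))
                    times = _place_spikes(rng, count, spec.stim_ms, m_early, m_late)
                    for ts in times:
                        rows.append((neuron, temperature, intensity, trial, ts))
                    if traces is not None:
                        traces[(neuron, temperature, intensity, trial)] = (
                            _render_trace(spec, times, ap_w))
    spikes = pd.DataFrame(
        rows,
        columns=["neuron", "temperature", "intensity", "trial", "spike_time_ms"],
    )
    return SyntheticRecording(spikes=spikes, traces=traces, spec=spec)


def ground_truth_table(spec: GeneratorSpec) -> pd.DataFrame:
    """Generating sigmoid parameters per neuron and temperature plus their
    exact Q10s (for parameter-recovery tests)."""
    t_cold, t_hot = spec.temperatures
    delta_t = t_hot - t_cold
    rows = []
    for neuron in range(spec.n_neurons):
        cold = spec.response_at(neuron, t_cold)
        hot = spec.response_at(neuron, t_hot)
        for name in ("sat", "i50", "width"):
            c = getattr(cold, name)
            h = getattr(hot, name)
            rows.append({
                "neuron": neuron,
                "param": name,
                "cold": c,
                "hot": h,
                "q10": (h / c) ** (10.0 / delta_t),
            })
    return pd.DataFrame(rows)


def write_dataset(rec: SyntheticRecording, directory: str | Path) -> Path:
    """Persist as one directory per neuron with a tabular spike-times file,
    plus ground truth and the generator spec."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for neuron, group in rec.spikes.groupby("neuron"):
        ndir = directory / f"neuron_{int(neuron):02d}"
        ndir.mkdir(exist_ok=True)
        group[["temperature", "intensity", "trial", "spike_time_ms"]].to_csv(
            ndir / "spikes.csv", index=False)
    ground_truth_table(rec.spec).to_csv(directory / "ground_truth.csv", index=False)
    meta = asdict(rec.spec)
    meta["cold_responses"] = [
        list(r.as_array()) for r in rec.spec.neuron_cold_responses()]
    (directory / "spec.json").write_text(json.dumps(meta, indent=2))
    if rec.traces:
        tdir = directory / "traces"
        tdir.mkdir(exist_ok=True)
        for (neuron, temp, intensity, trial), V in rec.traces.items():
            np.save(tdir / f"n{neuron:02d}_t{temp}_i{intensity}_r{trial}.npy", V)
    return directory


def load_dataset(directory: str | Path) -> pd.DataFrame:
    """Load the tidy spike table of a dataset directory (any dataset
    following the same layout, not only generated ones)."""
    directory = Path(directory)
    frames = []
    for ndir in sorted(directory.glob("neuron_*")):
        df = pd.read_csv(ndir / "spikes.csv")
        df.insert(0, "neuron", int(ndir.name.split("_")[1]))
        frames.append(df)
    if not frames:
        raise FileNotFoundError(f"no neuron_* directories under {directory}")
    return pd.concat(frames, ignore_index=True)
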