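"""Analysis of intracellular-recording-like datasets.

Works on the tidy spike table produced by :mod:`thermospike.synth` (or
any dataset in the same layout): extracts spikes from voltage traces by
an adaptive threshold, fits three-parameter sigmoids to rate-level
curves, quantifies temperature effects as Q10s with box-plot statistics
(1.5 IQR whisker rule) and nonparametric tests, and measures
action-potential width at half-maximum and early/late adaptation ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .model import detect_spikes
from .sweep import q10_of
from .transduction import SigmoidResponse

__all__ = [
    "NeuronResponseSummary",
    "extract_spikes",
    "fit_response_curve",
    "trial_rate_table",
    "summarize_neurons",
    "q10_statistics",
    "ap_widths",
    "waveform_metrics",
    "early_late_ratios",
]


# ---------------------------------------------------------------------------
# spike extraction from traces
# ---------------------------------------------------------------------------

def extract_spikes(
    trace: np.ndarray,
    fs_hz: float,
    pre_samples: int,
    k: float = 5.0,
    noise_floor_mv: float = 1.0,
    lockout_ms: float = 1.0,
    confirm_ms: float = 1.0,
) -> np.ndarray:
    """Spike times (ms, relative to stimulus onset) from a sampled trace.

    The detection threshold is the pre-stimulus median plus ``k`` times a
    robust noise scale (1.4826 * MAD of the pre-stimulus window), floored
    at ``noise_floor_mv`` so noise-free traces remain detectable.  A
    crossing only counts when the trace climbs at least half the
    threshold margin further within ``confirm_ms`` — action potentials
    overshoot the threshold by far, noise excursions hover at it.
    """
    trace = np.asarray(trace, dtype=float)
    if pre_samples < 2:
        raise ValueError("a pre-stimulus window is required for thresholding")
    pre = trace[:pre_samples]
    baseline = float(np.median(pre))
    noise = 1.4826 * float(np.median(np.abs(pre - baseline)))
    margin = max(k * noise, noise_floor_mv)
    threshold = baseline + margin
    t = (np.arange(trace.size) - pre_samples) / fs_hz * 1000.0
    candidates = detect_spikes(t, trace, threshold=threshold, lockout_ms=0.0)
    n_confirm = max(int(round(confirm_ms * fs_hz / 1000.0)), 1)
    kept: list[float] = []
    for ts in candidates:
        i = int(np.searchsorted(t, ts))
        if np.max(trace[i:i + n_confirm]) < threshold + 0.5 * margin:
            continue
        if kept and ts - kept[-1] < lockout_ms:
            continue
        kept.append(float(ts))
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# rate-level curves
# ---------------------------------------------------------------------------

def fit_response_curve(
    intensities: np.ndarray, rates: np.ndarray, flag_r2: float = 0.5
) -> tuple[SigmoidResponse | None, float]:
    """Bounded least-squares fit of the three-parameter sigmoid to
    per-intensity mean rates.

    Returns ``(fit, R^2)``; non-sigmoidal data (R^2 below ``flag_r2``, or
    a degenerate constant response) is flagged by returning ``None`` for
    the fit.
    """
    intensities = np.asarray(intensities, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if intensities.size < 4:
        raise ValueError("need >= 4 intensities to fit a sigmoid")
    if np.ptp(rates) == 0:
        return None, 0.0
    r_max = float(rates.max())
    half = 0.5 * r_max
    i50_init = float(np.interp(half, rates, intensities)) if np.all(
        np.diff(rates) >= 0) else float(np.median(intensities))
    lo = np.array([1e-9, intensities.min() - 40.0, 1e-3])
    hi = np.array([4.0 * r_max + 1.0, intensities.max() + 40.0, 60.0])

    def resid(p):
        return SigmoidResponse(*p)(intensities) - rates

    sol = least_squares(
        resid,
        x0=np.clip([r_max, i50_init, 5.0], lo + 1e-9, hi - 1e-9),
        bounds=(lo, hi), xtol=1e-13, ftol=1e-13, gtol=1e-13,
    )
    fit = SigmoidResponse(*sol.x)
    pred = fit(intensities)
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - float(np.sum((rates - pred) ** 2)) / ss_tot
    if r2 < flag_r2:
        return None, r2
    return fit, r2


def trial_rate_table(
    spikes: pd.DataFrame,
    stim_ms: float = 100.0,
    trials: int | None = None,
    intensities: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-trial firing rates (Hz) over the stimulus window, including
    zero-spike trials (absent from the tidy spike table)."""
    if trials is None:
        trials = int(spikes["trial"].max()) + 1
    if intensities is None:
        intensities = np.sort(spikes["intensity"].unique())
    in_stim = spikes[(spikes["spike_time_ms"] >= 0)
                     & (spikes["spike_time_ms"] < stim_ms)]
    counts = in_stim.groupby(
        ["neuron", "temperature", "intensity", "trial"]).size()
    rows = []
    for neuron in np.sort(spikes["neuron"].unique()):
        for temperature in np.sort(spikes["temperature"].unique()):
            for intensity in intensities:
                for trial in range(trials):
                    c = counts.get((neuron, temperature, intensity, trial), 0)
                    rows.append((neuron, temperature, intensity, trial,
                                 c / (stim_ms / 1000.0)))
    return pd.DataFrame(
        rows, columns=["neuron", "temperature", "intensity", "trial", "rate"])


# ---------------------------------------------------------------------------
# per-neuron summaries
# ---------------------------------------------------------------------------

@dataclass
class NeuronResponseSummary:
    """Fits and temperature coefficients for one neuron."""

    neuron: int
    t_cold: float
    t_hot: float
    fit_cold: SigmoidResponse | None
    fit_hot: SigmoidResponse | None
    r2_cold: float
    r2_hot: float
    mean_rates: pd.DataFrame
    q10: dict[str, float] = field(default_factory=dict)

    @property
    def delta_t(self) -> float:
        return self.t_hot - self.t_cold


_Q10_OBSERVABLES = ("sat", "i50", "width", "rate_at_cold_i50", "slope_at_cold_i50")


def summarize_neurons(
    spikes: pd.DataFrame,
    stim_ms: float = 100.0,
    trials: int | None = None,
) -> tuple[list[NeuronResponseSummary], pd.DataFrame]:
    """Sigmoid fits at both temperatures per neuron, plus Q10s of the
    saturation rate, half-max level, dynamic-range width, and the rate
    and slope evaluated at the cold half-max intensity (fixed-stimulus
    comparison).  Returns the summaries and a tidy population frame."""
    rates = trial_rate_table(spikes, stim_ms, trials)
    temperatures = np.sort(spikes["temperature"].unique())
    if temperatures.size != 2:
        raise ValueError("expected exactly two temperatures")
    t_cold, t_hot = float(temperatures[0]), float(temperatures[1])
    summaries = []
    rows = []
    for neuron, group in rates.groupby("neuron"):
        mean_rates = group.groupby(["temperature", "intensity"])["rate"].mean()
        fits = {}
        r2s = {}
        for T in (t_cold, t_hot):
            sub = mean_rates.loc[T]
            fits[T], r2s[T] = fit_response_curve(
                sub.index.to_numpy(), sub.to_numpy())
        summary = NeuronResponseSummary(
            neuron=int(neuron), t_cold=t_cold, t_hot=t_hot,
            fit_cold=fits[t_cold], fit_hot=fits[t_hot],
            r2_cold=r2s[t_cold], r2_hot=r2s[t_hot],
            mean_rates=mean_rates.reset_index(),
        )
        if fits[t_cold] is not None and fits[t_hot] is not None:
            fc, fh = fits[t_cold], fits[t_hot]
            i50_cold = fc.i50
            obs_cold = {
                "sat": fc.sat, "i50": fc.i50, "width": fc.width,
                "rate_at_cold_i50": float(fc(np.array(i50_cold))),
                "slope_at_cold_i50": fc.slope_at(i50_cold),
            }
            obs_hot = {
                "sat": fh.sat, "i50": fh.i50, "width": fh.width,
                "rate_at_cold_i50": float(fh(np.array(i50_cold))),
                "slope_at_cold_i50": fh.slope_at(i50_cold),
            }
            for name in _Q10_OBSERVABLES:
                c, h = obs_cold[name], obs_hot[name]
                summary.q10[name] = (
                    q10_of(c, h, summary.delta_t) if c > 0 and h > 0 else np.nan)
        summaries.append(summary)
        row = {"neuron": int(neuron), "r2_cold": r2s[t_cold], "r2_hot": r2s[t_hot]}
        row.update({f"q10_{k}": v for k, v in summary.q10.items()})
        rows.append(row)
    return summaries, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

def _box_stats(values: np.ndarray) -> dict:
    """Median/quartiles with outliers outside [q1 - 1.5 iqr, q3 + 1.5 iqr]."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo) & (values <= hi)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(inside.min()) if inside.size else float("nan"),
        "whisker_high": float(inside.max()) if inside.size else float("nan"),
        "outliers": values[(values < lo) | (values > hi)].tolist(),
        "n": int(values.size),
    }


def _signed_rank(values: np.ndarray, reference: float):
    """Wilcoxon signed-rank p-value of the median against ``reference``.

    Exact distribution for n <= 25 (scipy's exact mode), normal
    approximation with mid-rank ties above.  All-tied samples are
    untestable and return None; samples identical to the reference give
    p = 1 by convention (no evidence of a shift).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    diffs = values - reference
    if np.all(diffs == 0):
        return 1.0
    if np.ptp(values) == 0:
        # all tied at a value != reference: sign test degenerates, but the
        # signed-rank statistic is still defined
        pass
    n_eff = np.count_nonzero(diffs)
    try:
        if n_eff <= 25 and len(np.unique(np.abs(diffs[diffs != 0]))) == n_eff:
            res = stats.wilcoxon(diffs, mode="exact")
        else:
            res = stats.wilcoxon(diffs, mode="approx")
    except ValueError:
        return None
    return float(res.pvalue)


def q10_statistics(
    population: pd.DataFrame,
    rate_table: pd.DataFrame | None = None,
    references: tuple[float, ...] = (1.0, 1.5, 2.0),
) -> dict:
    """Distribution statistics and hypothesis tests for the Q10 columns.

    Per observable: box-plot summary (1.5 IQR whisker rule) and Wilcoxon
    signed-rank tests of the Q10 median against each reference.  When a
    trial-level ``rate_table`` is given, a two-sided rank-sum test
    comparing trial rates across temperatures is run per intensity.
    """
    if len(population) < 3:
        raise ValueError("need >= 3 neurons for population statistics")
    out: dict = {"observables": {}, "ranksum_by_intensity": None}
    for col in population.columns:
        if not col.startswith("q10_"):
            continue
        vals = population[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        entry = {"box": _box_stats(vals), "signed_rank": {}}
        for ref in references:
            entry["signed_rank"][str(ref)] = _signed_rank(vals, ref)
        out["observables"][col.removeprefix("q10_")] = entry
    if rate_table is not None:
        temps = np.sort(rate_table["temperature"].unique())
        by_intensity = {}
        for intensity, group in rate_table.groupby("intensity"):
            cold = group[group["temperature"] == temps[0]]["rate"].to_numpy()
            hot = group[group["temperature"] == temps[-1]]["rate"].to_numpy()
            if np.ptp(np.concatenate([cold, hot])) == 0:
                by_intensity[float(intensity)] = None
                continue
            by_intensity[float(intensity)] = float(
                stats.ranksums(cold, hot).pvalue)
        out["ranksum_by_intensity"] = by_intensity
    return out


# ---------------------------------------------------------------------------
# waveform metrics
# ---------------------------------------------------------------------------

def ap_widths(
    trace: np.ndarray,
    fs_hz: float,
    baseline: float | None = None,
) -> np.ndarray:
    """Width at half-maximum amplitude (ms) of every action potential.

    For each detected peak, the half-maximum level is the baseline plus
    half the peak's amplitude above baseline; the width is the time
    between the interpolated crossings around the peak.  Peaks truncated
    at the trace edges are excluded.
    """
    from scipy.signal import find_peaks

    trace = np.asarray(trace, dtype=float)
    if baseline is None:
        baseline = float(np.median(trace))
    span = trace.max() - baseline
    if span <= 0:
        return np.empty(0)
    peaks, _ = find_peaks(trace, prominence=0.5 * span)
    widths = []
    for p in peaks:
        half = baseline + 0.5 * (trace[p] - baseline)
        i = p
        while i > 0 and trace[i - 1] > half:
            i -= 1
        j = p
        while j < trace.size - 1 and trace[j + 1] > half:
            j += 1
        if i == 0 or j == trace.size - 1:
            continue  # truncated at an edge
        left = (i - 1) + (half - trace[i - 1]) / (trace[i] - trace[i - 1])
        right = j + (half - trace[j]) / (trace[j + 1] - trace[j])
        widths.append((right - left) / fs_hz * 1000.0)
    return np.asarray(widths)


def waveform_metrics(
    traces_by_temperature: dict[float, list[np.ndarray]],
    fs_hz: float,
) -> dict:
    """Pooled AP width per temperature and the Q10 of the median width."""
    temps = sorted(traces_by_temperature)
    if len(temps) != 2:
        raise ValueError("expected traces at exactly two temperatures")
    pooled = {}
    for T in temps:
        widths = [ap_widths(tr, fs_hz) for tr in traces_by_temperature[T]]
        widths = np.concatenate(widths) if widths else np.empty(0)
        pooled[T] = widths
    if any(pooled[T].size == 0 for T in temps):
        return {"widths": pooled, "q10_ap_width": None, "flag": "no APs detected"}
    med_cold = float(np.median(pooled[temps[0]]))
    med_hot = float(np.median(pooled[temps[1]]))
    return {
        "widths": pooled,
        "median_width": {temps[0]: med_cold, temps[1]: med_hot},
        "q10_ap_width": q10_of(med_cold, med_hot, temps[1] - temps[0]),
        "flag": None,
    }


def early_late_ratios(
    spikes: pd.DataFrame,
    early: tuple[float, float] = (10.0, 40.0),
    late: tuple[float, float] = (70.0, 100.0),
) -> pd.DataFrame:
    """Early-phase vs late-phase rate ratio per neuron and temperature."""
    rows = []
    for (neuron, temperature), group in spikes.groupby(["neuron", "temperature"]):
        ts = group["spike_time_ms"].to_numpy()
        n_trials_entries = group[["intensity", "trial"]].drop_duplicates()
        n_early = np.count_nonzero((ts >= early[0]) & (ts < early[1]))
        n_late = np.count_nonzero((ts >= late[0]) & (ts < late[1]))
        rate_early = n_early / (early[1] - early[0])
        rate_late = n_late / (late[1] - late[0])
        rows.append({
            "neuron": neuron, "temperature": temperature,
            "rate_early": rate_early, "rate_late": rate_late,
            "ratio": rate_early / rate_late if rate_late > 0 else np.nan,
        })
    return pd.DataFrame(rows)
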