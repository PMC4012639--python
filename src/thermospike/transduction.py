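"""Reverse-engineering the mechanotransduction sigmoid.

A receptor's rate-level curve r(I_dB) is modeled as the cascade of a
sigmoidal transduction stage theta (sound intensity in dB SPL -> receptor
current) and the spike-generation transfer function phi(I) =
A*sqrt(I - I0).  Given a representative target response at some
temperature and a spike-generation fit (A, I0), the transduction sigmoid
minimizing the squared error of the composed curve on a sound-intensity
grid is recovered by bounded multi-start least squares; Q10s of its three
parameters summarize how transduction would have to shift with
temperature to preserve the target response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SigmoidResponse",
    "RepresentativeConfig",
    "representative_response",
    "compose_response",
    "fit_transduction",
    "transduction_q10_distribution",
    "InfeasibleCompositionError",
    "DEFAULT_DB_GRID",
]

#: sound-intensity evaluation grid (dB SPL), matching the experimental
#: stimulus range, 1 dB steps
DEFAULT_DB_GRID = np.arange(32.0, 89.0, 1.0)

#: bounds for the transduction parameters (saturation current within the
#: characterized simulation range; half-max level and width in dB)
THETA_BOUNDS = ((1e-6, 0.0, 1e-3), (0.6, 120.0, 40.0))


class InfeasibleCompositionError(RuntimeError):
    """Raised when no feasible transduction can reach half the target."""


@dataclass(frozen=True)
class SigmoidResponse:
    """Three-parameter sigmoid: sat / (1 + exp(-(I_dB - i50) / width)).

    Used both for receptor rate-level curves (sat in Hz) and for
    transduction curves (sat in uA/mm^2).
    """

    sat: float
    i50: float
    width: float

    def __post_init__(self) -> None:
        if self.sat <= 0:
            raise ValueError("saturation must be > 0")
        if self.width <= 0:
            raise ValueError("dynamic-range width must be > 0")

    def __call__(self, i_db: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        i_db = np.asarray(i_db, dtype=float)
        return self.sat * expit((i_db - self.i50) / self.width)

    def slope_at(self, i_db: float) -> float:
        """Analytic derivative of the sigmoid at ``i_db`` (per dB)."""
        e = np.exp(-(i_db - self.i50) / self.width)
        return float(self.sat * e / (self.width * (1.0 + e) ** 2))

    def as_array(self) -> np.ndarray:
        return np.array([self.sat, self.i50, self.width])


@dataclass(frozen=True)
class RepresentativeConfig:
    """Median receptor response at the cold temperature plus its Q10s.

    The defaults are provisional fixture values chosen to be plausible
    for the recorded population (they are configuration, not published
    constants): cold response r_sat = 250 Hz, I50 = 55 dB, w = 3 dB at
    22 degC, with Q10s (1.25, 1.0, 0.9) for (sat, i50, width) — a
    moderate saturation-rate increase with heating, a temperature-stable
    half-max level, and a width that shrinks slightly with heating.
    """

    t_cold: float = 22.0
    cold: SigmoidResponse = SigmoidResponse(250.0, 55.0, 3.0)
    q10_sat: float = 1.25
    q10_i50: float = 1.0
    q10_width: float = 0.9

    def __post_init__(self) -> None:
        for q in (self.q10_sat, self.q10_i50, self.q10_width):
            if q <= 0:
                raise ValueError("Q10s must be > 0")


def representative_response(config: RepresentativeConfig, temperature: float) -> SigmoidResponse:
    """Scale each sigmoid parameter by Q10 ** ((T - T_cold) / 10)."""
    f = (temperature - config.t_cold) / 10.0
    return SigmoidResponse(
        sat=config.cold.sat * config.q10_sat**f,
        i50=config.cold.i50 * config.q10_i50**f,
        width=config.cold.width * config.q10_width**f,
    )


def compose_response(
    A: float, I0: float, theta: SigmoidResponse, i_db: np.ndarray | None = None
) -> np.ndarray:
    """Cascade rate-level curve r = A*sqrt(theta(I_dB) - I0), clamped to
    zero where the transduction current stays below threshold."""
    if A <= 0:
        raise ValueError("slope A must be > 0")
    if i_db is None:
        i_db = DEFAULT_DB_GRID
    return A * np.sqrt(np.maximum(theta(i_db) - I0, 0.0))


_DEFAULT_STARTS = (
    (0.4, 55.0, 4.0),
    (0.2, 50.0, 8.0),
    (0.55, 60.0, 2.0),
    (0.1, 45.0, 15.0),
    (0.3, 70.0, 6.0),
    (0.5, 40.0, 10.0),
)


def fit_transduction(
    A: float,
    I0: float,
    target: SigmoidResponse,
    i_db: np.ndarray | None = None,
    starts=_DEFAULT_STARTS,
) -> tuple[SigmoidResponse, float]:
    """Best-fit transduction sigmoid for one spike-generation model.

    Bounded nonlinear least squares of the composed response against the
    target on the dB grid, multi-start with the lowest-cost solution
    retained.  Returns the sigmoid and the R^2 of the composed curve.

    Raises :class:`InfeasibleCompositionError` when even the maximal
    feasible transduction current cannot drive the composed response to
    half the target's saturation.
    """
    if i_db is None:
        i_db = DEFAULT_DB_GRID
    y = target(i_db)
    reachable = A * np.sqrt(max(THETA_BOUNDS[1][0] - I0, 0.0))
    if reachable < 0.5 * target.sat:
        raise InfeasibleCompositionError(
            f"spike generation saturates at {reachable:.1f} Hz, "
            f"below half the target saturation {target.sat:.1f} Hz"
        )

    lo = np.array(THETA_BOUNDS[0])
    hi = np.array(THETA_BOUNDS[1])

    def resid(p):
        theta = SigmoidResponse(*p)
        return compose_response(A, I0, theta, i_db) - y

    best = None
    for start in starts:
        x0 = np.clip(start, lo + 1e-9, hi - 1e-9)
        sol = least_squares(resid, x0=x0, bounds=(lo, hi), xtol=1e-14,
                            ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    theta = SigmoidResponse(*best.x)
    pred = compose_response(A, I0, theta, i_db)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return theta, r2


def transduction_q10_distribution(
    sweep_table: pd.DataFrame,
    config: RepresentativeConfig | None = None,
    t_cold: float = 18.0,
    t_hot: float = 28.0,
    i_db: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-model transduction fits at both temperatures and their Q10s.

    ``sweep_table`` must carry the square-root fit columns
    (A_cold, I0_cold, A_hot, I0_hot).  Models whose fits are missing or
    whose composition is infeasible are excluded and counted.  Returns
    the per-model frame and a summary dict with median/quartile/range
    statistics per parameter (whiskers cover the full data range).
    """
    config = config or RepresentativeConfig()
    delta_t = t_hot - t_cold
    rho_cold = representative_response(config, t_cold)
    rho_hot = representative_response(config, t_hot)

    rows = []
    n_failed = 0
    for rec in sweep_table.itertuples():
        try:
            a_c, i0_c = float(rec.A_cold), float(rec.I0_cold)
            a_h, i0_h = float(rec.A_hot), float(rec.I0_hot)
            if not (np.isfinite(a_c) and np.isfinite(a_h)):
                raise ValueError("missing fit")
            th_c, r2_c = fit_transduction(a_c, i0_c, rho_cold, i_db)
            th_h, r2_h = fit_transduction(a_h, i0_h, rho_hot, i_db)
        except (ValueError, InfeasibleCompositionError):
            n_failed += 1
            continue
        rows.append({
            "index": int(rec.index) if hasattr(rec, "index") else len(rows),
            "sat_cold": th_c.sat, "i50_cold": th_c.i50, "w_cold": th_c.width,
            "sat_hot": th_h.sat, "i50_hot": th_h.i50, "w_hot": th_h.width,
            "r2_cold": r2_c, "r2_hot": r2_h,
            "q10_sat": (th_h.sat / th_c.sat) ** (10.0 / delta_t),
            "q10_i50": (th_h.i50 / th_c.i50) ** (10.0 / delta_t),
            "q10_w": (th_h.width / th_c.width) ** (10.0 / delta_t),
        })
    frame = pd.DataFrame(rows)
    summary: dict = {"n_models": len(frame), "n_failed": n_failed}
    for col in ("q10_sat", "q10_i50", "q10_w"):
        if len(frame):
            vals = frame[col].to_numpy()
            summary[col] = {
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
    return frame, summary
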