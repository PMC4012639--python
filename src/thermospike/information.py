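"""Closed-form mean Fisher information for square-root f-I curves.

For a type I rate curve f(I) = A*sqrt(I - I0), Fisher information about
the input current under rate noise is J_P(I) = f'(I)^2 / f(I) (Poisson)
or J_G(I) = f'(I)^2 / sigma^2 (Gaussian).  Averaging J over the current
interval that maps onto a fixed firing-rate interval [f_min, f_max]
yields closed forms that depend on the curve only through A — so the
temperature coefficient of the average information is Q10(A)^4 for both
noise models, independent of threshold shifts and of the noise scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.integrate import quad

__all__ = [
    "FisherSpec",
    "mean_fisher",
    "fisher_q10",
    "information_lower_bound",
    "current_interval",
]

#: default firing-rate averaging interval (Hz); every Q10 conclusion is
#: independent of this choice (the interval cancels in the ratio)
DEFAULT_RATE_INTERVAL = (10.0, 300.0)


@dataclass(frozen=True)
class FisherSpec:
    """Specification of a mean-Fisher-information evaluation."""

    A: float
    f_min: float = DEFAULT_RATE_INTERVAL[0]
    f_max: float = DEFAULT_RATE_INTERVAL[1]
    noise: str = "poisson"       # "poisson" | "gauss"
    bin_ms: float = 1.0          # Poisson observation bin (cancels in J)
    sigma2: float = 1.0          # Gaussian rate variance

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("slope A must be > 0")
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")
        if self.noise not in ("poisson", "gauss"):
            raise ValueError("noise must be 'poisson' or 'gauss'")
        if self.sigma2 <= 0 or self.bin_ms <= 0:
            raise ValueError("noise scales must be > 0")


def mean_fisher(spec: FisherSpec) -> float:
    """Average Fisher information over the fixed rate interval.

    Poisson:  A^4 / (2 f_max f_min (f_max + f_min))
    Gaussian: A^4 ln(f_max / f_min) / (2 sigma^2 (f_max^2 - f_min^2))

    Both follow by integrating J over [I_min, I_max] with
    f = A*sqrt(I - I0), f' = A/2 (I - I0)^(-1/2); the Gaussian prefactor
    is fixed to be consistent with J_G = (f')^2 / sigma^2 (equivalently
    (f')^2 = A^2 / (4 (I - I0))).  Temperature enters only through A, so
    the Q10 of either average is Q10(A)^4.
    """
    A, fmin, fmax = spec.A, spec.f_min, spec.f_max
    if spec.noise == "poisson":
        return A**4 / (2.0 * fmax * fmin * (fmax + fmin))
    return A**4 * math.log(fmax / fmin) / (
        2.0 * spec.sigma2 * (fmax**2 - fmin**2))


def fisher_q10(q10_slope: float) -> float:
    """Q10 of the mean Fisher information: the fourth power of Q10(A),
    identically for both noise models."""
    if q10_slope <= 0:
        raise ValueError("Q10(A) must be > 0")
    return q10_slope**4


def current_interval(A: float, I0: float, f_min: float, f_max: float):
    """Invert f = A*sqrt(I - I0) at the rate-interval edges."""
    return I0 + (f_min / A) ** 2, I0 + (f_max / A) ** 2


def information_lower_bound(
    A: float,
    I0: float,
    f_min: float = DEFAULT_RATE_INTERVAL[0],
    f_max: float = DEFAULT_RATE_INTERVAL[1],
    noise: str = "poisson",
    sigma2: float = 1.0,
    j_func=None,
) -> float:
    """Low-noise capacity bound C_low = ln integral sqrt(J(I) / 2 pi e) dI
    over the current interval mapping onto [f_min, f_max].

    J is evaluated pointwise from the square-root rate model (or from an
    explicit ``j_func(I)`` override) and integrated by adaptive
    quadrature.  The bound is invariant to constant shifts of the current
    axis (I0) by construction.
    """
    spec = FisherSpec(A, f_min, f_max, noise, sigma2=sigma2)
    i_min, i_max = current_interval(A, I0, f_min, f_max)
    if not i_max > i_min:
        raise ValueError("empty integration interval")

    if j_func is not None:
        j_of_i = j_func
    elif noise == "poisson":
        def j_of_i(I):
            return A / 4.0 * (I - I0) ** -1.5
    else:
        def j_of_i(I):
            return A**2 / (4.0 * sigma2 * (I - I0))

    val, _ = quad(lambda I: math.sqrt(j_of_i(I) / (2.0 * math.pi * math.e)),
                  i_min, i_max, limit=200)
    return math.log(val)
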