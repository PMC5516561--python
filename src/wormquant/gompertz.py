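"""Gompertz mortality-law utilities.

Worm demography is conventionally summarised by the Gompertz law: the hazard
of death rises exponentially with age,

    h(t) = a * exp(b * t)

with a rate parameter ``a`` (baseline hazard, 1/day) and a shape parameter
``b`` (demographic rate of aging, 1/day).  The corresponding survival
function is S(t) = exp(-(a/b) * (exp(b*t) - 1)).  The b -> 0 limit is the
exponential (constant-hazard) law, which this module handles explicitly so
the same machinery can drive endpoint-style stress assays.

Mean lifespan under the Gompertz law has no elementary closed form, so it is
obtained by numerical integration of S(t); `calibrate_rate` inverts that
integral to find the rate parameter that yields a target mean lifespan at a
given shape parameter.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "gompertz_hazard",
    "gompertz_survival",
    "gompertz_mean",
    "calibrate_rate",
    "sample_gompertz",
]

# Below this shape value the law is treated as exponential (numerically the
# two are indistinguishable long before this point).
_B_EXPONENTIAL = 1e-9


def gompertz_hazard(t, a: float, b: float):
    """Hazard a*exp(b*t) at age ``t``."""
    t = np.asarray(t, dtype=float)
    return a * np.exp(b * t)


def gompertz_survival(t, a: float, b: float):
    """Survival probability S(t) at age ``t`` (vectorised)."""
    t = np.asarray(t, dtype=float)
    if a < 0 or b < 0:
        raise ValueError("Gompertz parameters must be non-negative")
    if a == 0:
        return np.ones_like(t)
    if b < _B_EXPONENTIAL:
        return np.exp(-a * t)
    return np.exp(-(a / b) * np.expm1(b * t))


def gompertz_mean(a: float, b: float) -> float:
    """Mean lifespan: numerical integral of S(t) over [0, inf)."""
    if a <= 0:
        raise ValueError("mean lifespan is infinite for zero hazard")
    if b < _B_EXPONENTIAL:
        return 1.0 / a
    # integrate to where the cumulative hazard reaches ~50 (S ~ e^-50)
    t_max = np.log1p(50.0 * b / a) / b
    val, _ = integrate.quad(
        lambda t: float(gompertz_survival(t, a, b)), 0.0, t_max, limit=200
    )
    return float(val)


def calibrate_rate(b: float, mean_lifespan: float) -> float:
    """Rate parameter ``a`` such that the Gompertz mean equals ``mean_lifespan``.

    The mean is strictly decreasing in ``a``, so the root is bracketed on a
    wide log10 grid and found by Brent's method.
    """
    if mean_lifespan <= 0:
        raise ValueError("mean_lifespan must be positive")
    if b < 0:
        raise ValueError("shape parameter must be non-negative")

    def f(log10_a: float) -> float:
        return gompertz_mean(10.0**log10_a, b) - mean_lifespan

    lo, hi = -15.0, 3.0
    if f(lo) < 0 or f(hi) > 0:  # pragma: no cover - defensive
        raise ValueError("target mean lifespan out of calibration range")
    root = optimize.brentq(f, lo, hi, xtol=1e-12)
    return float(10.0**root)


def sample_gompertz(a: float, b: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw death ages by inverting the survival function.

    With u ~ U(0,1), t = log1p(-(b/a) * log(u)) / b; zero hazard yields
    +inf (the worm never dies within any observation window).
    """
    if a < 0 or b < 0:
        raise ValueError("Gompertz parameters must be non-negative")
    u = rng.random(size)
    if a == 0:
        return np.full(size, np.inf)
    if b < _B_EXPONENTIAL:
        return -np.log(u) / a
    return np.log1p(-(b / a) * np.log(u)) / b
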