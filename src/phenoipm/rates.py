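"""Temperature-dependent development rates and the log-normal variability model.

Development in poikilotherms is tracked as *physiological age*: a
dimensionless quantity that accumulates at a temperature-dependent rate
``r[T]`` (per day) and triggers maturation when it crosses a threshold.
Two rate-curve families are provided:

``linear_degree_day``
    ``r(T) = slope * (T - base_temp)`` above ``base_temp``, zero below —
    the classic degree-day model.

``hump_nonlinear``
    A Logan-type curve ``r(T) = psi * (exp(rho*(T - t_base)) -
    exp(rho*(t_max - t_base) - (t_max - T)/delta))`` on
    ``[t_base, t_max]``, zero outside: exponential rise with temperature
    followed by a sharp collapse approaching the upper lethal threshold.

Individual development rates are modelled as log-normally distributed
around the temperature-dependent *median*: the per-step aging increment is
``LN(mu = ln(r[T] * dt), sigma^2)``, so ``exp(mu)`` — the median of the
increment — equals the deterministic rate-summation increment exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "RateCurve",
    "LogNormalRateSpec",
    "NoDevelopmentError",
    "median_rate",
    "hump_optimum",
    "rate_summation",
    "lognormal_increment_params",
]

_FAMILIES = ("linear_degree_day", "hump_nonlinear")


class NoDevelopmentError(ValueError):
    """Raised when the median rate is at/below the clip floor.

    ``ln(r * dt)`` is undefined at ``r = 0``; callers branch to the
    degenerate (no-aging) kernel or a zero increment instead.
    """


@dataclass(frozen=True)
class RateCurve:
    """A median development-rate curve ``r(T)`` in day^-1.

    Parameters
    ----------
    family
        ``"linear_degree_day"`` (params ``base_temp``, ``slope``) or
        ``"hump_nonlinear"`` (params ``psi``, ``rho``, ``t_max``,
        ``delta``, optional ``t_base``).
    params
        Named curve parameters.
    clip_floor
        Rates at or below this value (day^-1) are treated as exactly zero
        development; development halts in cold.
    """

    family: str
    params: Mapping[str, float]
    clip_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown rate family {self.family!r}; choose from {_FAMILIES}")
        if self.clip_floor < 0:
            raise ValueError("clip_floor must be >= 0")
        object.__setattr__(self, "params", dict(self.params))
        required = {
            "linear_degree_day": {"base_temp", "slope"},
            "hump_nonlinear": {"psi", "rho", "t_max", "delta"},
        }[self.family]
        missing = required - set(self.params)
        if missing:
            raise ValueError(f"{self.family} curve missing parameters {sorted(missing)}")

    def __call__(self, temp):
        return median_rate(self, temp)


def median_rate(curve: RateCurve, temp):
    """Evaluate the median rate (day^-1) at one or many temperatures."""
    t = np.asarray(temp, dtype=float)
    p = curve.params
    if curve.family == "linear_degree_day":
        r = p["slope"] * (t - p["base_temp"])
        r = np.maximum(r, 0.0)
    else:
        tb = p.get("t_base", 0.0)
        tmx = p["t_max"]
        rho, delta, psi = p["rho"], p["delta"], p["psi"]
        with np.errstate(over="ignore"):
            r = psi * (np.exp(rho * (t - tb)) - np.exp(rho * (tmx - tb) - (tmx - t) / delta))
        r = np.where((t < tb) | (t > tmx), 0.0, np.maximum(r, 0.0))
    return float(r) if np.isscalar(temp) else r


def hump_optimum(curve: RateCurve) -> float:
    """Temperature of peak development for a ``hump_nonlinear`` curve.

    Setting the derivative of the Logan form to zero gives
    ``T* = t_max - ln(rho*delta) / (rho - 1/delta)``.
    """
    if curve.family != "hump_nonlinear":
        raise ValueError("optimum is defined for the hump_nonlinear family")
    p = curve.params
    rho, delta = p["rho"], p["delta"]
    return p["t_max"] - np.log(rho * delta) / (rho - 1.0 / delta)


def rate_summation(curve: RateCurve, temps, dt: float = 1.0) -> np.ndarray:
    """Cumulative physiological age ``a(t_n) = sum_i r[T(t_i)] * dt``.

    The Riemann-sum accumulation of development over a censused
    temperature record; the returned series is nondecreasing and its
    ``n``-th entry is the age after ``n+1`` steps.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("temps must be nonempty")
    rates = median_rate(curve, temps)
    rates = np.where(rates > curve.clip_floor, rates, 0.0)
    return np.cumsum(rates * dt)


@dataclass(frozen=True)
class LogNormalRateSpec:
    """Log-normal development-rate variability around a median curve.

    ``sigma`` is the stage-specific scale parameter of the log-normal
    distribution (dimensionless); ``sigma = 0`` is the deterministic
    limit.  The location parameter is always derived as
    ``mu = ln(median_rate * dt)``.
    """

    sigma: float
    curve: RateCurve

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def lognormal_increment_params(
    spec: LogNormalRateSpec, temp: float, dt: float = 1.0
) -> tuple[float, float]:
    """Location/scale of the per-step aging-increment distribution.

    Returns ``(mu, sigma)`` with ``mu = ln(r[T] * dt)`` so the median
    increment equals the deterministic one.  Raises
    :class:`NoDevelopmentError` when the median rate is at/below the
    curve's clip floor (cold torpor): the caller must use the degenerate
    no-aging kernel or a zero draw.
    """
    r = median_rate(spec.curve, temp)
    if r <= spec.curve.clip_floor:
        raise NoDevelopmentError(
            f"median rate {r:.3g}/day at {temp:.2f} C is at/below the clip floor"
        )
    return float(np.log(r * dt)), spec.sigma
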