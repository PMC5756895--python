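"""Mountain pine beetle life cycle, cold mortality, and adult flight.

Wires the generic engine into the eight-stage mountain pine beetle
(*Dendroctonus ponderosae*) life cycle: egg, four larval instars, pupa,
teneral adult, adult.  Cold mortality is a step function of daily minimum
temperature (probability one strictly below -18 C, zero otherwise) applied
to the egg, pupal, teneral-adult, and adult stages; the larval instars are
cold-hardened and carry no mortality rule.  Emerged adults fly on days
whose maximum temperature strictly exceeds 18.3 C and settle out of the
flying pool at an exponential rate.

The per-stage rate-curve parameters bundled here are illustrative
defaults (Logan-type hump curves tuned to give a univoltine cycle under
the synthetic reference year); real applications should load fitted
parameters from a life-cycle config file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .forcing import SyntheticForcingConfig
from .ipm import StageSpec, Trajectory
from .rates import LogNormalRateSpec, RateCurve, hump_optimum, median_rate

__all__ = [
    "MortalityRule",
    "FlightModel",
    "TrapSeries",
    "FlightCurve",
    "cold_step_mortality",
    "flight_step",
    "initialize_from_start_times",
    "cumulative_flight_curve",
    "default_stages",
    "default_flight_model",
    "reference_forcing",
    "load_life_cycle",
    "save_life_cycle",
    "read_trap_csv",
    "STAGE_NAMES",
    "COLD_SENSITIVE_STAGES",
]

STAGE_NAMES = ["egg", "L1", "L2", "L3", "L4", "pupa", "teneral_adult", "adult"]
COLD_SENSITIVE_STAGES = ("egg", "pupa", "teneral_adult", "adult")


@dataclass(frozen=True)
class MortalityRule:
    """Per-step mortality probability from daily minimum temperature.

    ``cold_step`` kills with probability one strictly below ``threshold``
    (default -18 C) and zero at or above it; ``none`` never kills.
    """

    kind: str = "cold_step"
    threshold: float = -18.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "cold_step"):
            raise ValueError(f"unknown mortality kind {self.kind!r}")

    def probability(self, tmin: float) -> float:
        if self.kind == "none":
            return 0.0
        return 1.0 if tmin < self.threshold else 0.0


def cold_step_mortality(rule: MortalityRule, tmin: float) -> float:
    """The step-function mortality probability for a day's tmin."""
    return rule.probability(tmin)


@dataclass(frozen=True)
class FlightModel:
    """Threshold-triggered flight with exponential settling.

    Emerged adults take wing on days with tmax strictly above
    ``flight_threshold`` (C); each day a fraction
    ``1 - exp(-settling_rate * dt)`` of the flying pool settles.  The
    default settling rate corresponds to a 3-day flight half-life
    (illustrative; fit this to flight-mill or dispersal data).
    """

    flight_threshold: float = 18.3
    settling_rate: float = float(np.log(2) / 3.0)

    def __post_init__(self) -> None:
        if self.settling_rate <= 0:
            raise ValueError("settling_rate must be positive")

    def settle_probability(self, dt: float) -> float:
        return float(1.0 - np.exp(-self.settling_rate * dt))

    def step(
        self, emerged: float, flying: float, tmax: float, dt: float
    ) -> tuple[float, float, float, float]:
        """One day of flight dynamics; settling precedes take-off.

        Returns ``(emerged, flying, newly_settled, newly_flying)``; the
        three pools conserve mass.
        """
        if emerged < 0 or flying < 0:
            raise ValueError("pools must be nonnegative")
        newly_settled = flying * self.settle_probability(dt)
        flying -= newly_settled
        newly_flying = 0.0
        if tmax > self.flight_threshold:
            newly_flying = emerged
            flying += emerged
            emerged = 0.0
        return emerged, flying, newly_settled, newly_flying


def flight_step(
    emerged: float, flying: float, tmax: float, model: FlightModel, dt: float = 1.0
) -> tuple[float, float, float]:
    """Functional form of :meth:`FlightModel.step` (drops newly_flying)."""
    e, f, settled, _ = model.step(emerged, flying, tmax, dt)
    return e, f, settled


@dataclass(frozen=True)
class TrapSeries:
    """Daily trap-catch record with its normalized cumulative curve."""

    dates: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "dates", pd.DatetimeIndex(self.dates))
        if len(counts) != len(self.dates):
            raise ValueError("counts must match dates")
        if np.any(counts < 0):
            raise ValueError("trap counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def normalized_cumulative(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("trap series has zero total catch")
        return np.cumsum(self.counts) / self.total


def read_trap_csv(path, date_col: str = "date", count_col: str = "count") -> TrapSeries:
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    try:
        d, c = lower[date_col.lower()], lower[count_col.lower()]
    except KeyError as e:
        raise ValueError(f"trap CSV {path} lacks column {e}") from None
    dates = pd.to_datetime(df[d])
    order = np.argsort(dates.values)
    return TrapSeries(pd.DatetimeIndex(dates.iloc[order]), df[c].iloc[order].to_numpy(float))


def initialize_from_start_times(weights, egg_count: float) -> dict:
    """Distribute a brood over introduction dates proportional to weights.

    ``weights`` maps dates to nonnegative masses (e.g. the previous
    year's trap catches); the returned schedule introduces
    ``egg_count * w / sum(w)`` eggs at age zero on each date and conserves
    the total exactly.
    """
    if isinstance(weights, TrapSeries):
        weights = dict(zip(weights.dates, weights.counts))
    items = [(pd.Timestamp(k), float(v)) for k, v in weights.items()]
    if any(v < 0 for _, v in items):
        raise ValueError("start-time weights must be nonnegative")
    total = sum(v for _, v in items)
    if total <= 0:
        raise ValueError("start-time weights are all zero")
    return {k: egg_count * v / total for k, v in items if v > 0}


@dataclass(frozen=True)
class FlightCurve:
    """Normalized cumulative flight distribution of simulated adults."""

    dates: pd.DatetimeIndex
    cumulative_fraction: np.ndarray
    total_flown: float

    @property
    def empty(self) -> bool:
        return self.total_flown == 0


def cumulative_flight_curve(trajectory: Trajectory) -> FlightCurve:
    """Cumulative newly-flying mass over its eventual total, in [0, 1].

    Nondecreasing and exactly one on the final day whenever any flight
    occurred; a run with no flight yields a flagged empty curve rather
    than a division error.
    """
    if "newly_flying" not in trajectory.frame:
        raise ValueError("trajectory carries no flight pools; simulate with a flight model")
    newly = trajectory.frame["newly_flying"].to_numpy(float)
    dates = pd.DatetimeIndex(trajectory.frame["date"])
    cum = np.cumsum(newly)
    total = float(cum[-1])
    if total == 0:
        return FlightCurve(dates, np.zeros(len(dates)), 0.0)
    return FlightCurve(dates, cum / total, total)


def _hump(peak_rate: float, t_max: float, rho: float = 0.12, delta: float = 2.0,
          t_base: float = 5.0, clip_floor: float = 1e-8) -> RateCurve:
    """Logan hump curve scaled so its peak median rate equals ``peak_rate``."""
    raw = RateCurve("hump_nonlinear",
                    {"psi": 1.0, "rho": rho, "t_max": t_max, "delta": delta, "t_base": t_base},
                    clip_floor=clip_floor)
    peak = median_rate(raw, hump_optimum(raw))
    return RateCurve("hump_nonlinear",
                     {"psi": peak_rate / peak, "rho": rho, "t_max": t_max, "delta": delta,
                      "t_base": t_base}, clip_floor=clip_floor)


# Illustrative per-stage (peak median rate day^-1, upper threshold C, sigma);
# chosen once to give a univoltine cycle under the synthetic reference year.
_DEFAULTS = {
    "egg": (0.12, 30.0, 0.15),
    "L1": (0.16, 30.0, 0.20),
    "L2": (0.16, 31.0, 0.20),
    "L3": (0.12, 31.0, 0.20),
    "L4": (0.06, 30.0, 0.25),
    "pupa": (0.10, 30.0, 0.15),
    "teneral_adult": (0.08, 30.0, 0.20),
    "adult": (0.10, 30.0, 0.20),
}


def default_stages(cold_threshold: float = -18.0) -> list[StageSpec]:
    """The eight-stage mountain pine beetle life cycle with defaults.

    Cold-step mortality on egg, pupa, teneral adult, and adult; no
    mortality on the larval instars; ``gamma = 1`` throughout.
    """
    stages = []
    for name in STAGE_NAMES:
        peak, t_max, sigma = _DEFAULTS[name]
        rule = (
            MortalityRule("cold_step", cold_threshold)
            if name in COLD_SENSITIVE_STAGES
            else None
        )
        stages.append(
            StageSpec(
                name=name,
                rate_spec=LogNormalRateSpec(sigma, _hump(peak, t_max)),
                gamma=1.0,
                mortality=rule,
            )
        )
    return stages


def default_flight_model() -> FlightModel:
    return FlightModel()


def reference_forcing(seed: int = 0) -> SyntheticForcingConfig:
    """Synthetic stand-in for a Jasper-like mountain forcing record.

    Mid-July of one year through late September of the next (443 days):
    cool continental climate, strong seasonal cycle, winters that dip
    below the -18 C cold-mortality threshold, summers whose daily maxima
    clear the 18.3 C flight threshold.
    """
    return SyntheticForcingConfig(
        mean_annual=4.0,
        amplitude=16.0,
        peak_day=205,
        diurnal_range=10.0,
        noise_sd=3.0,
        noise_autocorr=0.6,
        n_days=443,
        seed=seed,
        start="2001-07-15",
    )


def _curve_to_dict(curve: RateCurve) -> dict:
    return {"family": curve.family, "params": dict(curve.params),
            "clip_floor": curve.clip_floor}


def save_life_cycle(path, stages: Sequence[StageSpec], flight: FlightModel | None = None) -> None:
    """Write a life-cycle configuration (stages + flight model) to YAML."""
    doc = {
        "stages": [
            {
                "name": s.name,
                "gamma": s.gamma,
                "sigma": s.rate_spec.sigma,
                "curve": _curve_to_dict(s.rate_spec.curve),
                "mortality": (
                    {"kind": s.mortality.kind, "threshold": s.mortality.threshold}
                    if s.mortality is not None
                    else {"kind": "none"}
                ),
            }
            for s in stages
        ]
    }
    if flight is not None:
        doc["flight"] = {
            "flight_threshold": flight.flight_threshold,
            "settling_rate": flight.settling_rate,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_life_cycle(path) -> tuple[list[StageSpec], FlightModel | None]:
    """Load stages and an optional flight model from a YAML config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    stages = []
    for entry in doc["stages"]:
        c = entry["curve"]
        curve = RateCurve(c["family"], c["params"], clip_floor=c.get("clip_floor", 1e-8))
        mort = entry.get("mortality", {"kind": "none"})
        rule = None
        if mort.get("kind", "none") != "none":
            rule = MortalityRule(mort["kind"], mort.get("threshold", -18.0))
        stages.append(
            StageSpec(
                name=entry["name"],
                rate_spec=LogNormalRateSpec(entry.get("sigma", 0.0), curve),
                gamma=entry.get("gamma", 1.0),
                mortality=rule,
            )
        )
    flight = None
    if "flight" in doc:
        f = doc["flight"]
        flight = FlightModel(f.get("flight_threshold", 18.3), f.get("settling_rate", np.log(2) / 3))
    return stages, flight
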