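"""Stochastic individual-based model of stage-structured development.

Each brood member is simulated separately: every step a fresh log-normal
aging increment is drawn for its current stage and added to its accrued
physiological age; when the accrued age exceeds the stage threshold the
individual advances to the next stage at age zero (excess development is
discarded).  Mortality, cold-step or otherwise, is evaluated with the rule
of the stage the individual occupied at the start of the step — the same
order (age, kill, then split) the integral projection engine uses, so the
IPM is the exact deterministic representation of this process.

The master seed deterministically spawns one child seed per replicate, so
whole runs are bit-reproducible while replicates stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forcing import TemperatureSeries
from .ipm import StageSpec
from .rates import LogNormalRateSpec, NoDevelopmentError, lognormal_increment_params

__all__ = ["IBMConfig", "IBMResult", "draw_increment", "step_ibm", "simulate_ibm"]

# stage codes beyond the staged life cycle
DEAD = -1


@dataclass(frozen=True)
class IBMConfig:
    """Brood size, replication, and seeding of the stochastic model."""

    n_individuals: int = 82
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")


def draw_increment(
    spec: LogNormalRateSpec, temp: float, dt: float, rng: np.random.Generator, size=None
):
    """Draw aging increment(s) from ``LN(ln(r[T] dt), sigma^2)``.

    Zero when the median rate is at/below the clip floor (no development
    in cold); exactly ``r * dt`` in the deterministic limit ``sigma = 0``.
    """
    try:
        mu, sigma = lognormal_increment_params(spec, temp, dt)
    except NoDevelopmentError:
        return 0.0 if size is None else np.zeros(size)
    if sigma == 0.0:
        med = float(np.exp(mu))
        return med if size is None else np.full(size, med)
    return rng.lognormal(mu, sigma, size=size)


@dataclass
class Individuals:
    """Vectorized state of one replicate's brood."""

    stage: np.ndarray  # int: stage index, n_stages = emerged, +1 flying, +2 settled, DEAD
    age: np.ndarray  # accrued physiological age within current stage

    @classmethod
    def brood(cls, n: int) -> "Individuals":
        return cls(np.zeros(n, dtype=int), np.zeros(n, dtype=float))


def step_ibm(
    pop: Individuals,
    temps_today: tuple[float, float, float],
    stages: Sequence[StageSpec],
    dt: float,
    rng: np.random.Generator,
    flight=None,
) -> None:
    """Advance every living individual one step, in place.

    Order per individual: draw and add the current stage's increment;
    survive the current stage's mortality (evaluated from tmin); if the
    accrued age now exceeds ``gamma``, advance one stage and reset the age
    to zero.  Completing the final stage moves the individual to the
    emerged pool; if a flight model is given, emerged individuals take
    wing on warm days (tmax above the flight threshold) and flying ones
    settle with the model's per-step probability.
    """
    tmin, tmean, tmax = temps_today
    n_stages = len(stages)
    EMERGED, FLYING, SETTLED = n_stages, n_stages + 1, n_stages + 2
    # individuals develop in the stage they occupied at the start of the
    # step: same-step recruits are neither aged nor killed again
    start_stage = pop.stage.copy()
    # emerged adults overwinter under the final stage's mortality rule
    last = stages[-1]
    if last.mortality is not None:
        emerged = start_stage == EMERGED
        if np.any(emerged):
            m = last.mortality.probability(tmin)
            if m > 0:
                idx = np.flatnonzero(emerged)
                pop.stage[idx[rng.random(idx.size) < m]] = DEAD
    for s, spec in enumerate(stages):
        here = start_stage == s
        if not np.any(here):
            continue
        k = int(here.sum())
        pop.age[here] += draw_increment(spec.rate_spec, tmean, dt, rng, size=k)
        if spec.mortality is not None:
            m = spec.mortality.probability(tmin)
            if m > 0:
                idx = np.flatnonzero(here)
                killed = idx[rng.random(k) < m]
                pop.stage[killed] = DEAD
        # at/above-threshold, with float slack so the deterministic limit
        # (n increments of exactly gamma/n) completes on step n; matches
        # the IPM's at/above-gamma split convention
        crossed = here & (pop.stage == s) & (pop.age >= spec.gamma * (1.0 - 1e-9))
        if np.any(crossed):
            pop.stage[crossed] = s + 1 if s + 1 < n_stages else EMERGED
            pop.age[crossed] = 0.0
    if flight is not None:
        # settling applies to those already airborne at the start of the
        # day; today's emergers (and any emerged backlog) then take wing
        flying = start_stage == FLYING
        if np.any(flying):
            p_settle = flight.settle_probability(dt)
            idx = np.flatnonzero(flying)
            pop.stage[idx[rng.random(idx.size) < p_settle]] = SETTLED
        if tmax > flight.flight_threshold:
            pop.stage[pop.stage == EMERGED] = FLYING


@dataclass
class IBMResult:
    """Per-replicate daily trajectories plus across-replicate summaries."""

    counts: np.ndarray  # (n_replicates, n_days, n_pools)
    dates: pd.DatetimeIndex
    pool_names: list[str]

    @property
    def mean(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.mean(axis=0), index=self.dates, columns=self.pool_names)

    @property
    def se(self) -> pd.DataFrame:
        n = self.counts.shape[0]
        sd = self.counts.std(axis=0, ddof=1) if n > 1 else np.zeros_like(self.counts[0])
        return pd.DataFrame(sd / np.sqrt(n), index=self.dates, columns=self.pool_names)

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy frame: replicate, date, pool, count."""
        reps, days, pools = self.counts.shape
        rec = []
        for r in range(reps):
            for p, name in enumerate(self.pool_names):
                rec.append(
                    pd.DataFrame(
                        {
                            "replicate": r,
                            "date": self.dates,
                            "pool": name,
                            "count": self.counts[r, :, p],
                        }
                    )
                )
        return pd.concat(rec, ignore_index=True)


def simulate_ibm(
    series: TemperatureSeries,
    stages: Sequence[StageSpec],
    cfg: IBMConfig,
    *,
    flight=None,
    introductions: dict | None = None,
    dt: float | None = None,
) -> IBMResult:
    """Run replicate stochastic simulations of the full brood.

    Individuals start in the first stage at age zero on day one, or on
    the dates of an ``introductions`` schedule (mass interpreted as an
    individual count, rounded).  Returns daily counts per stage and pool
    for every replicate; across-replicate mean and standard error are
    available on the result.
    """
    if dt is None:
        dt = series.step_days
    n_stages = len(stages)
    pool_names = [s.name for s in stages] + ["emerged", "flying", "settled", "dead"]
    n_days = len(series)
    out = np.zeros((cfg.n_replicates, n_days, len(pool_names)))
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)

    intro = None
    if introductions:
        intro = {pd.Timestamp(k): int(round(v)) for k, v in introductions.items()}
        if sum(intro.values()) <= 0:
            raise ValueError("introduction schedule adds no individuals")

    for r in range(cfg.n_replicates):
        rng = np.random.default_rng(children[r])
        if intro is None:
            pop = Individuals.brood(cfg.n_individuals)
        else:
            pop = Individuals(np.empty(0, dtype=int), np.empty(0, dtype=float))
        for i, date in enumerate(series.dates):
            if intro is not None and date in intro:
                add = intro[date]
                pop.stage = np.concatenate([pop.stage, np.zeros(add, dtype=int)])
                pop.age = np.concatenate([pop.age, np.zeros(add)])
            temps = (float(series.tmin[i]), float(series.tmean[i]), float(series.tmax[i]))
            step_ibm(pop, temps, stages, dt, rng, flight=flight)
            for p in range(n_stages + 3):
                out[r, i, p] = np.count_nonzero(pop.stage == p)
            out[r, i, -1] = np.count_nonzero(pop.stage == DEAD)
    return IBMResult(out, series.dates, pool_names)
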