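"""Flight-phenology validation and trajectory comparison.

Predicted flight-time distributions are compared with observed trap
catches by a two-sample Kolmogorov-Smirnov test on the aligned empirical
cumulative curves: the statistic is the maximum absolute difference of
the two ECDFs over the union of their supports, and the p-value comes
from the asymptotic Kolmogorov distribution at the effective sample size
``n_obs * n_pred / (n_obs + n_pred)``.  Failing to reject the null that
the two distributions coincide (p above the chosen level) is a positive
validation result.

Two sample-size conventions are supported: ``"records"`` counts the rows
of the time series (the reporting convention for trap data), and
``"counts"`` counts individual trapped insects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .ipm import Trajectory

__all__ = ["EcdfPair", "ecdf_pair", "ks_two_sample", "trajectory_discrepancy"]


@dataclass(frozen=True)
class EcdfPair:
    """Two empirical CDFs aligned on the union of their supports."""

    support: np.ndarray
    f_obs: np.ndarray
    f_pred: np.ndarray
    n_obs: float
    n_pred: float

    def __post_init__(self) -> None:
        for name in ("support", "f_obs", "f_pred"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.support) == len(self.f_obs) == len(self.f_pred)):
            raise ValueError("support and curves must have equal length")
        if len(self.support) == 0:
            raise ValueError("empty ECDF pair")
        for f in (self.f_obs, self.f_pred):
            if np.any(np.diff(f) < -1e-12) or f[-1] < 1 - 1e-9 or np.any(f < -1e-12):
                raise ValueError("ECDFs must be nondecreasing in [0, 1] ending at 1")
        if self.n_obs < 1 or self.n_pred < 1:
            raise ValueError("effective sample sizes must be >= 1")


def _weighted_ecdf(times, weights) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if t.size == 0 or w.sum() <= 0:
        raise ValueError("ECDF requires at least one positively weighted sample")
    if np.any(w < 0):
        raise ValueError("ECDF weights must be nonnegative")
    order = np.argsort(t, kind="stable")
    t, w = t[order], w[order]
    uniq, idx = np.unique(t, return_index=True)
    cum = np.add.reduceat(w, idx).cumsum() / w.sum()
    return uniq, cum


def ecdf_pair(
    obs_times,
    pred_times,
    obs_weights=None,
    pred_weights=None,
    n_convention: str = "records",
) -> EcdfPair:
    """Build aligned observed/predicted ECDFs from weighted samples.

    Times may be numbers or datetimes (converted to days).  Weights are
    frequency weights — each trapped insect is one sample.  The reported
    sample sizes follow ``n_convention``: ``"records"`` (number of rows
    with positive weight) or ``"counts"`` (total weight).
    """
    if n_convention not in ("records", "counts"):
        raise ValueError("n_convention must be 'records' or 'counts'")

    def as_float(x):
        x = pd.Index(x)
        if x.dtype.kind == "M":
            return x.asi8 / 86_400e9
        return np.asarray(x, dtype=float)

    to, tp = as_float(obs_times), as_float(pred_times)
    so, fo = _weighted_ecdf(to, obs_weights)
    sp, fp = _weighted_ecdf(tp, pred_weights)
    support = np.union1d(so, sp)
    # right-continuous step interpolation of each ECDF onto the union
    f_obs = np.concatenate([[0.0], fo])[np.searchsorted(so, support, side="right")]
    f_pred = np.concatenate([[0.0], fp])[np.searchsorted(sp, support, side="right")]

    def eff_n(times, weights):
        w = np.ones(len(times)) if weights is None else np.asarray(weights, dtype=float)
        return float(np.count_nonzero(w > 0)) if n_convention == "records" else float(w.sum())

    return EcdfPair(support, f_obs, f_pred, eff_n(to, obs_weights), eff_n(tp, pred_weights))


def ks_two_sample(pair: EcdfPair) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value for an ECDF pair.

    ``D = max |F_obs - F_pred|`` over the union support; ``p`` is the
    survival function of the Kolmogorov distribution evaluated at
    ``sqrt(n_eff) * D`` with ``n_eff = n_obs n_pred / (n_obs + n_pred)``.
    """
    d = float(np.max(np.abs(pair.f_obs - pair.f_pred)))
    en = pair.n_obs * pair.n_pred / (pair.n_obs + pair.n_pred)
    p = float(np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    if d == 0.0:
        p = 1.0
    return d, p


def trajectory_discrepancy(a: Trajectory, b: Trajectory) -> pd.DataFrame:
    """Per-stage max-abs and integrated-abs differences of two runs.

    Symmetric, zero iff the trajectories are identical; requires matching
    dates and stage columns (e.g. an IPM run vs its coarse cohort
    counterpart on the same forcing).
    """
    if a.stage_names != b.stage_names:
        raise ValueError("trajectories track different stages")
    fa, fb = a.frame, b.frame
    if len(fa) != len(fb) or not (fa["date"].values == fb["date"].values).all():
        raise ValueError("trajectories cover different dates")
    rows = []
    for name in a.stage_names:
        diff = np.abs(fa[name].to_numpy(float) - fb[name].to_numpy(float))
        rows.append({"stage": name, "max_abs": diff.max(), "integrated_abs": diff.sum()})
    return pd.DataFrame(rows).set_index("stage")
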