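"""Daily temperature forcing: reading, validation, and synthesis.

The simulation engine is driven by a daily record of minimum, mean, and
maximum air temperature.  Development uses the daily mean, cold mortality
the daily minimum, and adult flight the daily maximum, so all three
channels must be present (a mean-only record is expanded with a warning).

A synthetic generator produces a seasonal sinusoid with AR(1) noise on the
mean and a fixed diurnal half-range, so the full model can be exercised
without any station data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TemperatureSeries",
    "SyntheticForcingConfig",
    "read_temperature_csv",
    "generate_synthetic_series",
    "affine_bark_transform",
]


@dataclass(frozen=True)
class TemperatureSeries:
    """A validated daily (or uniformly sub-daily) temperature record.

    Parameters
    ----------
    dates
        Strictly increasing, uniformly spaced timestamps.
    tmin, tmean, tmax
        Temperatures in degrees Celsius, one value per date, with
        ``tmin <= tmean <= tmax`` everywhere.
    step_days
        Census interval in days (1.0 for daily records).
    """

    dates: pd.DatetimeIndex
    tmin: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    step_days: float = 1.0

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        tmin = np.asarray(self.tmin, dtype=float)
        tmean = np.asarray(self.tmean, dtype=float)
        tmax = np.asarray(self.tmax, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "tmin", tmin)
        object.__setattr__(self, "tmean", tmean)
        object.__setattr__(self, "tmax", tmax)
        n = len(dates)
        if not (len(tmin) == len(tmean) == len(tmax) == n):
            raise ValueError("temperature channels must match the date index length")
        if n == 0:
            raise ValueError("empty temperature series")
        for name, arr in (("tmin", tmin), ("tmean", tmean), ("tmax", tmax)):
            if not np.all(np.isfinite(arr)):
                bad = dates[~np.isfinite(arr)]
                raise ValueError(f"non-finite {name} at {list(bad)}")
        if n > 1:
            deltas = np.diff(dates.asi8)
            if np.any(deltas <= 0):
                dup = dates[1:][deltas <= 0]
                raise ValueError(f"dates not strictly increasing at {list(dup)}")
            if np.any(deltas != deltas[0]):
                expected = pd.Timedelta(days=self.step_days)
                missing = []
                for i, d in enumerate(deltas):
                    if d != deltas[0]:
                        missing.append(str(dates[i] + expected))
                raise ValueError(f"non-uniform date spacing; gap after/at {missing}")
        bad = (tmin > tmean) | (tmean > tmax)
        if np.any(bad):
            raise ValueError(
                f"channel ordering tmin <= tmean <= tmax violated on {list(dates[bad])}"
            )
        if self.step_days <= 0:
            raise ValueError("step_days must be positive")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "tmin": self.tmin, "tmean": self.tmean, "tmax": self.tmax}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SyntheticForcingConfig:
    """Parameters of the synthetic seasonal forcing generator.

    ``tmean(d) = mean_annual + amplitude * cos(2*pi*(doy - peak_day)/365.25)
    + AR(1) noise``; tmin/tmax are a symmetric half diurnal range around the
    mean.  The AR(1) noise has stationary standard deviation ``noise_sd``
    and lag-1 autocorrelation ``noise_autocorr``.
    """

    mean_annual: float = 4.0
    amplitude: float = 16.0
    peak_day: int = 200
    diurnal_range: float = 8.0
    noise_sd: float = 2.0
    noise_autocorr: float = 0.7
    n_days: int = 365
    seed: int = 0
    start: str = "2001-01-01"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.noise_autocorr < 1:
            raise ValueError("noise_autocorr must be in [0, 1)")
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")


_CANONICAL = {"date": "date", "tmin": "tmin", "tmean": "tmean", "tmax": "tmax"}


def read_temperature_csv(
    path,
    dialect: dict | None = None,
    interpolate_gaps: bool = False,
) -> TemperatureSeries:
    """Read a daily temperature CSV into a validated :class:`TemperatureSeries`.

    Parameters
    ----------
    path
        CSV with a header row; needs a date column and at least a mean
        temperature column.
    dialect
        Optional mapping from canonical names (``date``, ``tmin``,
        ``tmean``, ``tmax``) to the column names used in the file.
        Matching is case-insensitive.
    interpolate_gaps
        If True, isolated missing temperature *values* are linearly
        interpolated; missing *dates* are always a hard error.
    """
    mapping = dict(_CANONICAL)
    if dialect:
        mapping.update(dialect)
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}

    def col(name: str) -> str | None:
        want = mapping[name].lower()
        return lower.get(want)

    date_col = col("date")
    if date_col is None:
        raise ValueError(f"no date column ({mapping['date']!r}) in {path}")
    dates = pd.to_datetime(df[date_col])
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].tolist()
        raise ValueError(f"duplicated dates in {path}: {dup}")
    order = np.argsort(dates.values)
    df = df.iloc[order].reset_index(drop=True)
    dates = pd.DatetimeIndex(dates.iloc[order])

    tmean_col = col("tmean")
    if tmean_col is None:
        raise ValueError(f"no mean-temperature column ({mapping['tmean']!r}) in {path}")
    tmean = df[tmean_col].astype(float).to_numpy()
    tmin_col, tmax_col = col("tmin"), col("tmax")
    if tmin_col is None or tmax_col is None:
        logger.warning(
            "only a mean-temperature column found in %s; setting tmin = tmax = tmean",
            path,
        )
        tmin = tmean.copy()
        tmax = tmean.copy()
    else:
        tmin = df[tmin_col].astype(float).to_numpy()
        tmax = df[tmax_col].astype(float).to_numpy()

    if len(dates) > 1:
        deltas = np.diff(dates.asi8)
        step = np.min(deltas)
        gaps = np.nonzero(deltas != step)[0]
        if gaps.size:
            missing = [str(dates[i] + pd.Timedelta(step, "ns")) for i in gaps]
            raise ValueError(f"missing dates in {path}: {missing}")
        step_days = step / 86_400e9
    else:
        step_days = 1.0

    if interpolate_gaps:
        tmin, tmean, tmax = (
            pd.Series(a).interpolate(limit_area="inside").to_numpy()
            for a in (tmin, tmean, tmax)
        )
    for name, arr in (("tmin", tmin), ("tmean", tmean), ("tmax", tmax)):
        if np.any(~np.isfinite(arr)):
            bad = dates[~np.isfinite(arr)]
            raise ValueError(f"missing {name} values in {path} at {list(bad)}")
    if np.any(tmin > tmax):
        bad = dates[tmin > tmax]
        raise ValueError(f"tmin > tmax in {path} on {list(bad)}")
    # a mean that strays outside [tmin, tmax] is clipped silently by neither
    # channel: it is a data error
    if np.any((tmean < tmin) | (tmean > tmax)):
        bad = dates[(tmean < tmin) | (tmean > tmax)]
        raise ValueError(f"tmean outside [tmin, tmax] in {path} on {list(bad)}")
    return TemperatureSeries(dates, tmin, tmean, tmax, step_days=step_days)


def generate_synthetic_series(cfg: SyntheticForcingConfig) -> TemperatureSeries:
    """Generate a reproducible synthetic daily forcing series."""
    rng = np.random.default_rng(cfg.seed)
    dates = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")
    doy = dates.day_of_year.to_numpy(dtype=float)
    seasonal = cfg.mean_annual + cfg.amplitude * np.cos(
        2 * np.pi * (doy - cfg.peak_day) / 365.25
    )
    noise = np.zeros(cfg.n_days)
    if cfg.noise_sd > 0:
        phi = cfg.noise_autocorr
        innov_sd = cfg.noise_sd * np.sqrt(1.0 - phi * phi)
        eps = rng.normal(0.0, innov_sd, size=cfg.n_days)
        noise[0] = rng.normal(0.0, cfg.noise_sd)
        for i in range(1, cfg.n_days):
            noise[i] = phi * noise[i - 1] + eps[i]
    tmean = seasonal + noise
    half = cfg.diurnal_range / 2.0
    return TemperatureSeries(dates, tmean - half, tmean, tmean + half)


def affine_bark_transform(
    series: TemperatureSeries, slope: float = 1.0, offset: float = 0.0
) -> TemperatureSeries:
    """Map air temperatures to under-bark temperatures with an affine law.

    The default ``(slope=1, offset=0)`` is the identity.  Channels are
    re-sorted per day so the tmin <= tmean <= tmax invariant survives a
    negative slope.
    """
    chans = np.sort(
        np.stack(
            [slope * series.tmin + offset, slope * series.tmean + offset, slope * series.tmax + offset]
        ),
        axis=0,
    )
    return TemperatureSeries(
        series.dates, chans[0], chans[1], chans[2], step_days=series.step_days
    )
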