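import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import phenoipm as pp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_constant_series(n_days: int, temp: float, diurnal: float = 0.0):
    """A flat forcing record at one temperature (tmin = tmax = tmean +/- half range)."""
    cfg = pp.SyntheticForcingConfig(
        mean_annual=temp, amplitude=0.0, noise_sd=0.0, diurnal_range=diurnal,
        n_days=n_days, seed=0,
    )
    return pp.generate_synthetic_series(cfg)


@pytest.fixture
def constant_series():
    return make_constant_series


@pytest.fixture
def fig2_spec():
    """Single stage with median rate 0.5/day at 10 C and sigma = 0.2."""
    curve = pp.RateCurve("linear_degree_day", {"base_temp": 0.0, "slope": 0.05})
    return pp.StageSpec("s1", pp.LogNormalRateSpec(0.2, curve), gamma=1.0)


def make_three_stages(sigma: float = 0.2):
    """Three mortality-free stages with distinct rates at 10 C."""
    slopes = {"A": 0.020, "B": 0.015, "C": 0.025}
    return [
        pp.StageSpec(
            name,
            pp.LogNormalRateSpec(
                sigma, pp.RateCurve("linear_degree_day", {"base_temp": 0.0, "slope": s})
            ),
            gamma=1.0,
        )
        for name, s in slopes.items()
    ]


@pytest.fixture
def three_stages():
    return make_three_stages()


@pytest.fixture(scope="session")
def reference_series():
    return pp.generate_synthetic_series(pp.reference_forcing(0))


@pytest.fixture(scope="session")
def mpb_stages():
    return pp.default_stages()


@pytest.fixture(scope="session")
def reference_trajectory(reference_series, mpb_stages):
    """Full MPB reference-year IPM run with flight, 82 eggs on 30 July."""
    return pp.simulate_ipm(
        reference_series,
        mpb_stages,
        init=None,
        introductions={"2001-07-30": 82.0},
        flight=pp.default_flight_model(),
    )
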