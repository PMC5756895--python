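import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import phenoipm as pp
from tests.conftest import make_constant_series, make_three_stages

SPEC_05 = pp.LogNormalRateSpec(
    0.2, pp.RateCurve("linear_degree_day", {"base_temp": 0.0, "slope": 0.05})
)  # median rate 0.5/day at 10 C


class TestBuildKernel:
    def test_sums_to_one(self):
        g = pp.AgeGrid(512, 4.0)
        k = pp.build_kernel(SPEC_05, 10.0, 1.0, g)
        assert abs(k.increments.sum() - 1.0) <= 1e-12

    def test_random_parameterizations_sum_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            g = pp.AgeGrid(int(rng.integers(16, 513)), float(rng.uniform(0.5, 8.0)))
            spec = pp.LogNormalRateSpec(
                float(rng.uniform(0.01, 0.5)),
                pp.RateCurve("linear_degree_day",
                             {"base_temp": 0.0, "slope": float(rng.uniform(0.001, 0.2))}),
            )
            k = pp.build_kernel(spec, float(rng.uniform(1, 35)), 1.0, g)
            assert abs(k.increments.sum() - 1.0) <= 1e-12

    def test_kernel_mean_matches_lognormal_mean(self):
        # closed form exp(mu + sigma^2/2) = 0.5101 for rate .5, sigma .2
        g = pp.AgeGrid(512, 4.0)
        k = pp.build_kernel(SPEC_05, 10.0, 1.0, g)
        assert k.mean == pytest.approx(0.5 * np.exp(0.02), abs=g.bin_width)

    def test_cold_gives_degenerate_identity_kernel(self):
        g = pp.AgeGrid(128, 4.0)
        k = pp.build_kernel(SPEC_05, -10.0, 1.0, g)
        assert k.is_degenerate
        d = pp.AgeDistribution.point_mass(g, 50.0)
        out = pp.convolve_step(d, k)
        np.testing.assert_array_equal(out.mass, d.mass)

    def test_coarse_grid_warning(self, caplog):
        g = pp.AgeGrid(16, 4.0)  # bin width 0.25 cannot resolve sigma*r ~ 0.002
        spec = pp.LogNormalRateSpec(
            0.01, pp.RateCurve("linear_degree_day", {"base_temp": 0.0, "slope": 0.01})
        )
        with caplog.at_level(logging.WARNING, logger="phenoipm.ipm"):
            pp.build_kernel(spec, 10.0, 1.0, g)
        assert any("too coarse" in r.message for r in caplog.records)


class TestConvolveStep:
    def test_mass_conserved(self):
        g = pp.AgeGrid(256, 4.0)
        rng = np.random.default_rng(5)
        d = pp.AgeDistribution(g, rng.random(256) * 3.0, overflow=1.5)
        k = pp.build_kernel(SPEC_05, 10.0, 1.0, g)
        out = pp.convolve_step(d, k)
        assert out.total == pytest.approx(d.total, rel=1e-10)

    def test_grid_mismatch_rejected(self):
        d = pp.AgeDistribution.point_mass(pp.AgeGrid(128, 4.0), 1.0)
        k = pp.build_kernel(SPEC_05, 10.0, 1.0, pp.AgeGrid(256, 4.0))
        with pytest.raises(ValueError):
            pp.convolve_step(d, k)

    def test_repeated_convolution_matches_iid_sum_monte_carlo(self):
        # after n steps a point mass becomes the law of a sum of n iid
        # log-normals; check mean and variance against 10^5 draws
        n_steps, n_mc = 6, 100_000
        g = pp.AgeGrid(2048, 8.0)
        k = pp.build_kernel(SPEC_05, 10.0, 1.0, g)
        d = pp.AgeDistribution.point_mass(g, 1.0)
        for _ in range(n_steps):
            d = pp.convolve_step(d, k)
        assert d.overflow < 1e-9
        ages = d.grid.ages
        mean = float(d.mass @ ages)
        var = float(d.mass @ (ages - mean) ** 2)
        rng = np.random.default_rng(17)
        draws = rng.lognormal(np.log(0.5), 0.2, size=(n_steps, n_mc)).sum(axis=0)
        se_mean = draws.std(ddof=1) / np.sqrt(n_mc)
        assert mean == pytest.approx(draws.mean(), abs=3 * se_mean + g.bin_width)
        se_var = draws.var(ddof=1) * np.sqrt(2.0 / (n_mc - 1))
        assert var == pytest.approx(draws.var(ddof=1), abs=3 * se_var + g.bin_width)


class TestApplyMortality:
    def test_zero_is_identity(self):
        g = pp.AgeGrid(32, 4.0)
        d = pp.AgeDistribution.point_mass(g, 10.0)
        np.testing.assert_array_equal(pp.apply_mortality(d, 0.0).mass, d.mass)

    def test_one_empties_the_stage(self):
        g = pp.AgeGrid(32, 4.0)
        d = pp.AgeDistribution(g, np.ones(32), overflow=2.0)
        out = pp.apply_mortality(d, 1.0)
        assert out.total == 0.0

    def test_scalar_scaling(self):
        g = pp.AgeGrid(32, 4.0)
        d = pp.AgeDistribution(g, np.full(32, 2.5))
        assert pp.apply_mortality(d, 0.25).total == pytest.approx(60.0)

    @pytest.mark.parametrize("m", [-0.1, 1.1])
    def test_out_of_range_rejected(self, m):
        g = pp.AgeGrid(32, 4.0)
        with pytest.raises(ValueError):
            pp.apply_mortality(pp.AgeDistribution.point_mass(g, 1.0), m)


class TestSplitAtThreshold:
    def test_no_mass_above_threshold(self):
        g = pp.AgeGrid(128, 4.0)
        d = pp.AgeDistribution.point_mass(g, 7.0)
        retained, crossed = pp.split_at_threshold(d, 1.0)
        assert crossed == 0.0
        np.testing.assert_array_equal(retained.mass, d.mass)

    def test_all_mass_above_threshold(self):
        g = pp.AgeGrid(128, 4.0)
        m = np.zeros(128)
        m[100] = 4.0  # age 3.125 >> gamma
        d = pp.AgeDistribution(g, m, overflow=1.0)
        retained, crossed = pp.split_at_threshold(d, 1.0)
        assert crossed == pytest.approx(5.0)
        assert retained.total == 0.0

    def test_boundary_cell_split_in_half_when_gamma_on_grid_point(self):
        g = pp.AgeGrid(128, 4.0)  # gamma=1 sits exactly on grid point 32
        m = np.zeros(128)
        m[32] = 10.0
        _, crossed = pp.split_at_threshold(pp.AgeDistribution(g, m), 1.0)
        assert crossed == pytest.approx(5.0)

    @given(
        gamma=st.floats(0.05, 3.9),
        seed=st.integers(0, 2**16),
        overflow=st.floats(0, 5),
    )
    def test_conservation(self, gamma, seed, overflow):
        g = pp.AgeGrid(64, 4.0)
        rng = np.random.default_rng(seed)
        d = pp.AgeDistribution(g, rng.random(64), overflow=overflow)
        retained, crossed = pp.split_at_threshold(d, gamma)
        assert retained.total + crossed == pytest.approx(d.total, rel=1e-12)
        assert retained.overflow == 0.0


class TestStepStageSystem:
    def test_cold_no_mortality_is_a_fixed_point(self, three_stages):
        grids = [pp.AgeGrid.for_stage(s.gamma) for s in three_stages]
        state = pp.PopulationState.point_mass(three_stages, grids, 40.0)
        out = pp.step_stage_system(state, (-20.0, -20.0, -15.0), three_stages)
        np.testing.assert_array_equal(out.stage_totals, state.stage_totals)
        assert out.dead == 0.0

    def test_recruits_enter_next_stage_at_age_zero(self, three_stages):
        grids = [pp.AgeGrid.for_stage(s.gamma, n_bins=256) for s in three_stages]
        state = pp.PopulationState.point_mass(three_stages, grids, 100.0)
        for _ in range(80):
            state = pp.step_stage_system(state, (5.0, 10.0, 15.0), three_stages)
            # any mass in stage B beyond its own accrual must have entered at bin 0
        assert state.stage_totals[1] > 0

    def test_mass_ledger_closes_every_step(self, three_stages):
        grids = [pp.AgeGrid.for_stage(s.gamma, n_bins=256) for s in three_stages]
        state = pp.PopulationState.point_mass(three_stages, grids, 82.0)
        for _ in range(120):
            state = pp.step_stage_system(state, (5.0, 10.0, 15.0), three_stages)
            assert state.total == pytest.approx(82.0, rel=1e-9)

    def test_deterministic_limit_crossing_day(self):
        # sigma ~ 0, r = 0.1/day, gamma = 1: rate summation crosses on step 10
        curve = pp.RateCurve("linear_degree_day", {"base_temp": 0.0, "slope": 0.01})
        spec = pp.StageSpec("s", pp.LogNormalRateSpec(0.01, curve), gamma=1.0)
        series = make_constant_series(11, 10.0)
        traj = pp.simulate_ipm(series, [spec], init=100.0, n_bins=1024)
        in_stage = traj.frame["s"].to_numpy()
        assert 100.0 - in_stage[8] < 50.0  # < half crossed by step 9
        assert 100.0 - in_stage[9] >= 50.0  # >= half crossed by step 10


class TestBookkeepingEquivalence:
    def test_truncation_equals_difference_form(self):
        # the stage-linkage difference form (cumulative crossers now minus
        # previously) must reproduce the native truncation flux exactly
        stages = make_three_stages()
        series = make_constant_series(10, 12.0)
        a = pp.recruitment_series(series, stages, 50.0, n_bins=128, form="truncate")
        b = pp.recruitment_series(series, stages, 50.0, n_bins=128, form="difference")
        cols = [c for c in a.columns if c != "date"]
        np.testing.assert_allclose(a[cols].to_numpy(), b[cols].to_numpy(), atol=1e-10)

    def test_difference_form_requires_no_mortality(self, mpb_stages):
        series = make_constant_series(5, 12.0)
        with pytest.raises(ValueError):
            pp.recruitment_series(series, mpb_stages, 10.0, form="difference")


class TestTotalDensity:
    def test_point_mass_of_100(self):
        g = pp.AgeGrid(128, 4.0)
        assert pp.total_density(pp.AgeDistribution.point_mass(g, 100.0)) == 100.0

    def test_empty_distribution(self):
        assert pp.total_density(pp.AgeDistribution.empty(pp.AgeGrid(128, 4.0))) == 0.0

    def test_additive_over_disjoint_supports(self):
        g = pp.AgeGrid(128, 4.0)
        a = np.zeros(128); a[:10] = 1.0
        b = np.zeros(128); b[50:60] = 2.0
        da, db = pp.AgeDistribution(g, a), pp.AgeDistribution(g, b)
        dsum = pp.AgeDistribution(g, a + b)
        assert pp.total_density(dsum) == pytest.approx(
            pp.total_density(da) + pp.total_density(db))


class TestSimulate:
    def test_cold_day_leaves_totals_unchanged(self, three_stages):
        series = make_constant_series(1, -10.0)
        traj = pp.simulate_ipm(series, three_stages, init=30.0)
        assert traj.frame[ [s.name for s in three_stages] ].iloc[0].sum() == pytest.approx(30.0)

    def test_fig2_age_distribution_mean_grows_linearly(self, fig2_spec):
        # mean age after n steps = n * exp(ln 0.5 + 0.2^2/2) = n * 0.5101
        spec = pp.StageSpec("s1", fig2_spec.rate_spec, gamma=np.inf)
        state = pp.PopulationState([pp.AgeDistribution.point_mass(
            pp.AgeGrid(2048, 8.0), 100.0)])
        for i in range(5):
            state = pp.step_stage_system(state, (10.0, 10.0, 10.0), [spec])
            d = state.stages[0]
            mean_age = float(d.mass @ d.grid.ages) / d.total
            assert mean_age == pytest.approx((i + 1) * 0.5101, abs=2 * d.grid.bin_width)

    def test_bit_identical_across_runs(self, three_stages):
        series = make_constant_series(30, 12.0)
        a = pp.simulate_ipm(series, three_stages, init=82.0)
        b = pp.simulate_ipm(series, three_stages, init=82.0)
        assert a.frame.equals(b.frame)

    def test_cohort_at_128_bins_is_the_ipm_bit_for_bit(self, three_stages):
        series = make_constant_series(30, 12.0)
        a = pp.simulate_ipm(series, three_stages, init=82.0, n_bins=128)
        b = pp.simulate_cohort(series, three_stages, init=82.0, n_bins=128)
        assert a.frame.equals(b.frame)

    def test_resolution_sweep_discrepancy_nonincreasing(self, reference_series, mpb_stages):
        intro = {"2001-07-30": 82.0}
        ref = pp.simulate_ipm(reference_series, mpb_stages, init=None,
                              introductions=intro, n_bins=128, a_max_mult=1.5)
        disc = []
        for nb in (16, 32, 64, 128):
            t = pp.simulate_ipm(reference_series, mpb_stages, init=None,
                                introductions=intro, n_bins=nb, a_max_mult=1.5)
            disc.append(pp.trajectory_discrepancy(ref, t)["max_abs"].max())
        assert disc[0] >= disc[1] >= disc[2] >= disc[3]
        assert disc[3] == 0.0
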