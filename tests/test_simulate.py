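import numpy as np
import pytest

from icc_intervals import (
    DesignSpec,
    InfeasibleTargetError,
    ScenarioSpec,
    gamma_kurtosis,
    gamma_skewness,
    generate,
    generate_stack,
    point_icc_b,
    point_icc_w,
    solve_variance_components,
)
from icc_intervals.simulate import _draw_family, mean_squares_stack

DESIGN = DesignSpec(48, 3, 1)


class TestSolveVarianceComponents:
    @pytest.mark.parametrize(
        "icc_b, icc_w, expected",
        [
            (0.70, 0.99, (0.70, 0.29, 0.01)),
            (0.70, 0.70, (0.70, 0.0, 0.30)),
            (0.90, 0.94, (0.90, 0.04, 0.06)),
        ],
    )
    def test_component_targets(self, icc_b, icc_w, expected):
        vc = solve_variance_components(icc_b, icc_w, 1.0)
        assert (vc.sigma2_b, vc.sigma2_l, vc.sigma2_e) == pytest.approx(expected)

    def test_round_trip_through_point_estimates(self):
        vc = solve_variance_components(0.63, 0.87, 2.5)
        assert point_icc_b(vc) == pytest.approx(0.63)
        assert point_icc_w(vc) == pytest.approx(0.87)

    def test_infeasible_ordering_rejected(self):
        with pytest.raises(InfeasibleTargetError):
            solve_variance_components(0.9, 0.7, 1.0)


class TestFamilyAnalytics:
    def test_gamma_shape_moments(self):
        assert round(gamma_skewness(3), 2) == 1.15
        assert gamma_kurtosis(3) == pytest.approx(5.0)
        assert round(gamma_skewness(10), 2) == 0.63
        assert gamma_kurtosis(10) == pytest.approx(3.6)

    def test_mixture_location_solves_variance(self):
        # target variance 10/9 gives mixture means +/-1 with component sd 1/3
        sd = np.sqrt(10.0 / 9.0)
        m = 3.0 * sd / np.sqrt(10.0)
        assert m == pytest.approx(1.0)
        assert m / 3.0 == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("family", ["normal", "uniform", "mixture", "gamma"])
    def test_moment_matching_at_one_million_draws(self, family):
        rng = np.random.default_rng(314)
        sd = 0.83
        x = _draw_family(rng, family, sd, (1_000_000,), alpha=3.0)
        assert x.var() == pytest.approx(sd**2, rel=0.01)
        assert abs(x.mean()) < 3 * sd / 1000.0  # 3 standard errors of the mean

    def test_uniform_draws_bounded(self):
        rng = np.random.default_rng(1)
        sd = 0.5
        x = _draw_family(rng, "uniform", sd, (200_000,), alpha=3.0)
        assert np.max(np.abs(x)) <= sd * np.sqrt(3.0) + 1e-12

    def test_gamma_sample_skewness(self):
        rng = np.random.default_rng(2)
        x = _draw_family(rng, "gamma", 1.0, (1_000_000,), alpha=3.0)
        skew = np.mean(x**3) / np.mean(x**2) ** 1.5
        assert skew == pytest.approx(gamma_skewness(3.0), abs=0.03)


class TestGenerate:
    def test_seed_determinism(self):
        spec = ScenarioSpec(design=DESIGN, icc_b=0.7, icc_w=0.9, family="gamma", seed=8)
        assert np.array_equal(generate(spec).values, generate(spec).values)

    def test_different_seeds_differ(self):
        a = ScenarioSpec(design=DESIGN, icc_b=0.7, icc_w=0.9, seed=1)
        b = ScenarioSpec(design=DESIGN, icc_b=0.7, icc_w=0.9, seed=2)
        assert not np.array_equal(generate(a).values, generate(b).values)

    def test_zero_variance_component_is_constant_term(self):
        spec = ScenarioSpec(design=DESIGN, icc_b=0.7, icc_w=0.7, family="normal", seed=4)
        grid = generate(spec)
        # sigma2_l = 0: no rater main effect, so rater means differ only through errors
        rater_means = grid.values.mean(axis=(0, 2))
        assert rater_means.std() < 0.2

    def test_mean_level_applied(self):
        spec = ScenarioSpec(design=DESIGN, icc_b=0.7, icc_w=0.9, mu=50.0, seed=4)
        assert generate(spec).grand_mean == pytest.approx(50.0, abs=1.0)

    def test_family_validation(self):
        with pytest.raises(ValueError):
            ScenarioSpec(design=DESIGN, icc_b=0.7, icc_w=0.9, family="cauchy")

    def test_empirical_icc_recovered_across_families(self):
        # large design so moment estimates of the ICCs are tight
        big = DesignSpec(600, 40, 1)
        for family in ("normal", "uniform", "mixture", "gamma"):
            spec = ScenarioSpec(
                design=big, icc_b=0.70, icc_w=0.90, family=family, seed=55
            )
            ms = mean_squares_stack(generate(spec).values[None, ...], big)[0]
            from icc_intervals import AnovaSummary, estimate_variance_components

            vc = estimate_variance_components(AnovaSummary(*ms, design=big))
            assert point_icc_b(vc) == pytest.approx(0.70, abs=0.08)
            assert point_icc_w(vc) == pytest.approx(0.90, abs=0.05)


class TestGenerateStack:
    def test_stack_shape_and_determinism(self):
        spec = ScenarioSpec(design=DESIGN, icc_b=0.7, icc_w=0.99, seed=12)
        a = generate_stack(spec, 5)
        b = generate_stack(spec, 5)
        assert a.shape == (5, 48, 3, 1)
        assert np.array_equal(a, b)

    def test_stack_mean_squares_match_single_grid_path(self):
        from icc_intervals import DataGrid, compute_mean_squares

        spec = ScenarioSpec(design=DESIGN, icc_b=0.7, icc_w=0.9, seed=3)
        stack = generate_stack(spec, 4)
        ms = mean_squares_stack(stack, DESIGN)
        for i in range(4):
            s = compute_mean_squares(DataGrid(values=stack[i], design=DESIGN))
            assert ms[i] == pytest.approx((s.ms_subject, s.ms_rater, s.ms_error))
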