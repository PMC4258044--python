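import numpy as np
import pytest

from icc_intervals import (
    AnovaSummary,
    DataGrid,
    DesignSpec,
    UndefinedIccError,
    VarianceComponents,
    compute_mean_squares,
    estimate_variance_components,
    point_icc_b,
    point_icc_w,
)
from icc_intervals.errors import BalanceError, DesignError


class TestComputeMeanSquares:
    def test_constant_grid_has_zero_mean_squares(self):
        grid = DataGrid(values=np.full((3, 2, 1), 5.0), design=DesignSpec(3, 2, 1))
        s = compute_mean_squares(grid)
        assert (s.ms_subject, s.ms_rater, s.ms_error) == (0.0, 0.0, 0.0)

    def test_two_by_two_worked_example(self):
        grid = DataGrid(values=np.array([[1.0, 2.0], [3.0, 5.0]]), design=DesignSpec(2, 2, 1))
        s = compute_mean_squares(grid)
        assert s.ms_subject == pytest.approx(6.25)
        assert s.ms_rater == pytest.approx(2.25)
        assert s.ms_error == pytest.approx(0.25)

    def test_ss_df_consistency_matches_published_table(self):
        # published rater row: SS 39.73 on 9 df gives MS 4.414
        assert 39.73 / 9 == pytest.approx(4.414, abs=5e-4)

    def test_matches_statsmodels_two_way_anova(self, random_grid):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        from icc_intervals.io import grid_to_frame

        df = grid_to_frame(random_grid)
        fit = ols("value ~ C(subject) + C(rater)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        ours = compute_mean_squares(random_grid)
        assert ours.ms_subject == pytest.approx(table.loc["C(subject)", "mean_sq"])
        assert ours.ms_rater == pytest.approx(table.loc["C(rater)", "mean_sq"])
        assert ours.ms_error == pytest.approx(table.loc["Residual", "mean_sq"])

    def test_sum_of_squares_reconciles(self, random_grid):
        s = compute_mean_squares(random_grid)
        d = random_grid.design
        ss = (
            s.ms_subject * d.df_subject
            + s.ms_rater * d.df_rater
            + s.ms_error * d.df_error
        )
        total = float(np.sum((random_grid.values - random_grid.values.mean()) ** 2))
        assert ss == pytest.approx(total, rel=1e-12)

    def test_location_invariance_and_scale_equivariance(self, random_grid):
        base = compute_mean_squares(random_grid)
        shifted = compute_mean_squares(
            DataGrid(values=random_grid.values + 17.3, design=random_grid.design)
        )
        scaled = compute_mean_squares(
            DataGrid(values=2.5 * random_grid.values, design=random_grid.design)
        )
        for attr in ("ms_subject", "ms_rater", "ms_error"):
            assert getattr(shifted, attr) == pytest.approx(getattr(base, attr), abs=1e-9)
            assert getattr(scaled, attr) == pytest.approx(2.5**2 * getattr(base, attr))

    def test_bad_shapes_and_designs_raise(self):
        with pytest.raises(BalanceError):
            DataGrid(values=np.ones((3, 2, 2)), design=DesignSpec(3, 2, 1))
        with pytest.raises(DesignError):
            DesignSpec(1, 2, 1)
        with pytest.raises(BalanceError):
            DataGrid(values=np.array([[1.0, np.nan]] * 2), design=DesignSpec(2, 2, 1))


class TestVarianceComponents:
    def test_published_summary_inversion(self, rater_study_summary):
        vc = estimate_variance_components(rater_study_summary)
        assert vc.sigma2_b == pytest.approx(9.4664, abs=1e-4)
        assert vc.sigma2_l == pytest.approx(0.151167, abs=1e-6)
        assert vc.sigma2_e == pytest.approx(0.786)

    def test_equal_mean_squares_give_pure_error(self):
        s = AnovaSummary(3.0, 3.0, 3.0, design=DesignSpec(4, 3, 1))
        vc = estimate_variance_components(s)
        assert (vc.sigma2_b, vc.sigma2_l, vc.sigma2_e) == (0.0, 0.0, 3.0)

    def test_truncation_at_zero(self):
        s = AnovaSummary(0.5, 0.2, 1.0, design=DesignSpec(4, 3, 1))
        vc = estimate_variance_components(s)
        assert vc.sigma2_b == 0.0 and vc.sigma2_l == 0.0
        raw_b, raw_l, _ = s.raw_components()
        assert raw_b < 0 and raw_l < 0  # untruncated values kept available

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(-0.1, 0.2, 0.3)


class TestPointIcc:
    def test_published_point_estimates(self, rater_study_summary):
        vc = estimate_variance_components(rater_study_summary)
        assert round(point_icc_b(vc), 4) == 0.9099
        assert round(point_icc_w(vc), 4) == 0.9244

    @pytest.mark.parametrize(
        "vc, icc_b, icc_w",
        [
            (VarianceComponents(1.0, 0.0, 0.0), 1.0, 1.0),
            (VarianceComponents(0.0, 0.3, 0.7), 0.0, 0.3),
            (VarianceComponents(0.70, 0.29, 0.01), 0.70, 0.99),
            (VarianceComponents(0.4, 0.6, 0.0), 0.4, 1.0),
        ],
    )
    def test_boundary_and_forced_values(self, vc, icc_b, icc_w):
        assert point_icc_b(vc) == pytest.approx(icc_b)
        assert point_icc_w(vc) == pytest.approx(icc_w)

    def test_all_zero_components_undefined(self):
        with pytest.raises(UndefinedIccError):
            point_icc_b(VarianceComponents(0.0, 0.0, 0.0))

    def test_scale_invariance(self):
        vc = VarianceComponents(2.0, 1.0, 0.5)
        scaled = VarianceComponents(20.0, 10.0, 5.0)
        assert point_icc_b(vc) == pytest.approx(point_icc_b(scaled))
        assert point_icc_w(vc) == pytest.approx(point_icc_w(scaled))
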