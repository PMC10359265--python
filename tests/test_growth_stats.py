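"""Binning, summaries, regression, two-way ANOVA and divergence detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bonemorph.growth_stats import (
    BinningError,
    SexComparison,
    assign_bins,
    fit_growth_regression,
    group_summary,
    per_category_sex_tests,
    sex_divergence_age,
    two_way_anova,
)
from oracles import balanced_two_way_ss


def toy_table(values, ages=None, sexes=None):
    n = len(values)
    return pd.DataFrame({
        "case_id": [f"c{i}" for i in range(n)],
        "bone": "femur", "side": "R",
        "sex": sexes if sexes is not None else ["F"] * n,
        "age_years": ages if ages is not None else [10] * n,
        "height_cm": [140.0] * n,
        "femoral_length": values,
    })


class TestAssignBins:
    @pytest.mark.parametrize("height,expected", [
        (159.9, 155), (160.0, 160), (95.0, 95), (194.9, 190),
    ])
    def test_height_half_open_convention(self, height, expected):
        df = toy_table([30.0])
        df["height_cm"] = height
        assert assign_bins(df, "height")["height_category"].iloc[0] == expected

    def test_age_categories_span_4_to_18(self):
        df = toy_table([30.0] * 15, ages=list(range(4, 19)))
        out = assign_bins(df, "age")
        assert list(out["age_category"]) == list(range(4, 19))

    @pytest.mark.parametrize("axis,col,bad", [
        ("age", "age_years", 19), ("age", "age_years", 3),
        ("height", "height_cm", 94.9), ("height", "height_cm", 195.0),
    ])
    def test_out_of_range_rejected(self, axis, col, bad):
        df = toy_table([30.0])
        df[col] = bad
        with pytest.raises(BinningError):
            assign_bins(df, axis)


class TestGroupSummary:
    def test_mean_and_sample_sd(self):
        df = assign_bins(toy_table([10.0, 20.0, 30.0]), "age")
        out = group_summary(df, "femoral_length", "age_category")
        assert out["mean"].iloc[0] == 20.0
        assert out["sd"].iloc[0] == pytest.approx(10.0)
        assert out["n"].iloc[0] == 3

    def test_singleton_cell_has_undefined_sd(self):
        df = assign_bins(toy_table([42.0]), "age")
        out = group_summary(df, "femoral_length", "age_category")
        assert out["mean"].iloc[0] == 42.0
        assert np.isnan(out["sd"].iloc[0])

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(30, 2, 40)
        ages = rng.integers(4, 19, 40)
        df = assign_bins(toy_table(vals, ages=ages), "age")
        a = group_summary(df, "femoral_length", "age_category")
        b = group_summary(df.sample(frac=1, random_state=1), "femoral_length",
                          "age_category")
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))


class TestGrowthRegression:
    def test_hand_computed_oracle(self):
        """R and p match a from-scratch evaluation of the correlation and
        its t-test on the 5-point set."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 3, 2, 5, 4])
        df = toy_table(y, ages=[10] * 5)
        df["age_years"] = x
        res = fit_growth_regression(df, "femoral_length", "age")
        # independent closed-form computation
        r_exp = (((x - x.mean()) * (y - y.mean())).sum()
                 / np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum()))
        t_stat = r_exp * np.sqrt((5 - 2) / (1 - r_exp**2))
        p_exp = 2 * sps.t.sf(abs(t_stat), 5 - 2)
        assert res.R == pytest.approx(r_exp, abs=1e-12)
        assert res.p_value == pytest.approx(p_exp, abs=1e-12)
        slope_exp = r_exp * y.std(ddof=1) / x.std(ddof=1)
        assert res.slope == pytest.approx(slope_exp, abs=1e-12)

    def test_perfect_line(self):
        df = toy_table([1.0, 2, 3, 4], ages=[4, 5, 6, 7])
        res = fit_growth_regression(df, "femoral_length", "age")
        assert res.R == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_r_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        x = rng.normal(size=30)
        df = toy_table(y)
        df["height_cm"] = 150 + 10 * x
        df2 = df.copy()
        df2["height_cm"] = 150 + 25 * x  # affine rescale
        r1 = fit_growth_regression(df, "femoral_length", "height")
        r2 = fit_growth_regression(df2, "femoral_length", "height")
        assert r1.R == pytest.approx(r2.R, abs=1e-12)

    def test_null_correlation_is_small(self):
        rng = np.random.default_rng(11)
        df = toy_table(rng.normal(30, 5, 200), ages=rng.integers(4, 19, 200))
        res = fit_growth_regression(df, "femoral_length", "age")
        assert abs(res.R) < 0.2

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_growth_regression(toy_table([1.0, 2.0]), "femoral_length", "age")
        with pytest.raises(ValueError):
            fit_growth_regression(toy_table([1.0, 2.0, 3.0]), "femoral_length",
                                  "age")  # zero covariate variance


class TestTwoWayAnova:
    def balanced_table(self, rng, a_levels=3, n=8, cell_effects=None):
        rows = []
        for i, age in enumerate(range(6, 6 + a_levels)):
            for j, sex in enumerate(("F", "M")):
                mu = 30.0 if cell_effects is None else cell_effects[i][j]
                for _ in range(n):
                    rows.append((age, sex, mu + rng.normal()))
        df = pd.DataFrame(rows, columns=["age_years", "sex", "femoral_length"])
        df["case_id"] = [f"c{i}" for i in range(len(df))]
        df["bone"], df["side"], df["height_cm"] = "femur", "R", 140.0
        return assign_bins(df, "age")

    def test_balanced_type_ii_matches_brute_force(self):
        """On a balanced design, Type II SS equal the classical partitioned
        sums of squares within 1e-8 relative."""
        rng = np.random.default_rng(5)
        a_levels, n = 3, 8
        df = self.balanced_table(rng, a_levels, n,
                                 cell_effects=[[30, 31], [33, 30], [29, 34]])
        res = two_way_anova(df, "femoral_length", "age_category")
        y = np.zeros((a_levels, 2, n))
        for i, age in enumerate(range(6, 6 + a_levels)):
            for j, sex in enumerate(("F", "M")):
                y[i, j] = df[(df.age_years == age) & (df.sex == sex)][
                    "femoral_length"].to_numpy()
        oracle = balanced_two_way_ss(y, a_levels, 2)
        assert res.effects["category"]["ss"] == pytest.approx(
            oracle["ss_a"], rel=1e-8)
        assert res.effects["sex"]["ss"] == pytest.approx(oracle["ss_b"], rel=1e-8)
        assert res.effects["interaction"]["ss"] == pytest.approx(
            oracle["ss_ab"], rel=1e-8)
        assert res.effects["residual"]["ss"] == pytest.approx(
            oracle["ss_resid"], rel=1e-8)

    def test_single_level_factor_rejected(self):
        df = self.balanced_table(np.random.default_rng(0), a_levels=1)
        with pytest.raises(ValueError):
            two_way_anova(df, "femoral_length", "age_category")

    def test_empty_cell_falls_back_to_additive(self):
        rng = np.random.default_rng(1)
        df = self.balanced_table(rng)
        df = df[~((df.age_years == 6) & (df.sex == "M"))]
        with pytest.warns(UserWarning, match="interaction dropped"):
            res = two_way_anova(df, "femoral_length", "age_category")
        assert res.reduced_model
        assert "interaction" not in res.effects

    def test_welch_reduces_to_classical_t_with_equal_groups(self):
        """Equal n and equal variances: the Welch p equals the classical
        pooled t-test p to 1e-10."""
        rng = np.random.default_rng(2)
        f = rng.normal(30, 1, 20)
        m = f + 0.5  # identical spread, shifted
        df = toy_table(np.r_[f, m], ages=[10] * 40,
                       sexes=["F"] * 20 + ["M"] * 20)
        df = assign_bins(df, "age")
        comp = per_category_sex_tests(df, "femoral_length", "age_category")[0]
        p_classic = sps.ttest_ind(f, m, equal_var=True).pvalue
        assert comp.p_value == pytest.approx(p_classic, abs=1e-10)

    def test_small_cells_give_undefined_p(self):
        df = toy_table([30.0, 31.0, 32.0], ages=[10] * 3,
                       sexes=["F", "F", "M"])
        df = assign_bins(df, "age")
        comp = per_category_sex_tests(df, "femoral_length", "age_category")[0]
        assert np.isnan(comp.p_value)


class TestSexDivergenceAge:
    @staticmethod
    def mask_to_comparisons(mask):
        return [SexComparison(category=c, n_f=10, n_m=10, mean_f=0.0,
                              mean_m=1.0, p_value=0.01 if sig else 0.5)
                for c, sig in mask.items()]

    def test_clean_onset(self):
        mask = {a: a >= 13 for a in range(4, 19)}
        onset, out = sex_divergence_age(self.mask_to_comparisons(mask))
        assert onset == 13
        assert out == mask

    def test_all_nonsignificant_returns_none(self):
        mask = {a: False for a in range(4, 19)}
        onset, _ = sex_divergence_age(self.mask_to_comparisons(mask))
        assert onset is None

    def test_isolated_early_significance_ignored(self):
        """A lone significant category followed by non-significant ones does
        not count as the divergence onset."""
        mask = {a: (a == 7 or a >= 14) for a in range(4, 19)}
        onset, _ = sex_divergence_age(self.mask_to_comparisons(mask))
        assert onset == 14
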