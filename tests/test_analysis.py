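"""Covariate screening, correlations, regressions, moderation, extreme groups."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from entrate.analysis import (
    CohortStudy,
    apply_screening_rule,
    extreme_group_analysis,
    hierarchical_regression,
    moderation_analysis,
    pearson_ci,
    screen_covariates,
)
from entrate.simulate import CohortSimConfig, simulate_cohort


class TestPearsonCI:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_ci(x, x).r == pytest.approx(1.0)
        assert pearson_ci(x, -x).r == pytest.approx(-1.0)

    def test_six_point_toy_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 11.0])
        y = np.array([3.0, 1.0, 5.0, 9.0, 8.0, 13.0])
        # independent evaluation of the covariance formula
        xm, ym = x - x.mean(), y - y.mean()
        r_direct = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        res = pearson_ci(x, y)
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        assert res.ci_low <= res.r <= res.ci_high
        assert res.n == 6

    def test_fisher_interval_formula(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = pearson_ci(x, y)
        from scipy import stats

        half = stats.norm.ppf(0.975) / np.sqrt(50 - 3)
        assert res.ci_low == pytest.approx(np.tanh(np.arctanh(res.r) - half))
        assert res.ci_high == pytest.approx(np.tanh(np.arctanh(res.r) + half))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            pearson_ci([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])


class TestScreeningRule:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (0.126, 0.151, True),   # small effect, include
            (0.136, 0.160, True),
            (0.128, 0.141, True),
            (-0.054, 0.540, False),  # tiny effect, not significant
            (-0.058, 0.511, False),
            (0.10, 0.20, False),     # boundary: strict inequality
            (0.05, 0.01, True),      # tiny but significant
        ],
    )
    def test_inclusion_rule(self, r, p, expected):
        assert apply_screening_rule(r, p) is expected

    def test_screen_covariates_on_data(self):
        rng = np.random.default_rng(3)
        n = 400
        strong = rng.normal(size=n)
        weak = rng.normal(size=n)
        y = 0.4 * strong + rng.normal(size=n)
        df = pd.DataFrame(
            {
                "strong": strong,
                "weak": weak,
                "const": np.ones(n),
                "group": np.where(rng.random(n) < 0.5, "a", "b"),
                "y": y,
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            rep = screen_covariates(df, ["strong", "weak", "const", "group"], "y")
        assert "strong" in rep.included
        assert "weak" not in rep.included
        assert "const" not in rep.included
        assert rep.table.loc["group", "kind"] == "categorical"


class TestHierarchicalRegression:
    def test_noise_free_single_predictor(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"x": x, "y": 2.0 * x})
        table = hierarchical_regression(df, [["x"]], "y")
        step = table.steps[0]
        assert step.terms.loc["x", "beta"] == pytest.approx(2.0, abs=1e-10)
        assert step.terms.loc["x", "std_beta"] == pytest.approx(1.0, abs=1e-10)
        assert step.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_sole_predictor_std_beta_equals_zero_order_r(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=80)
        y = 0.3 * x + rng.normal(size=80)
        df = pd.DataFrame({"x": x, "y": y})
        table = hierarchical_regression(df, [["x"]], "y")
        r = pearson_ci(x, y).r
        assert table.steps[0].terms.loc["x", "std_beta"] == pytest.approx(
            r, abs=1e-10
        )

    def test_orthogonal_predictors_std_betas_equal_zero_order_rs(self):
        n = 64
        t = np.arange(n)
        x1 = np.sqrt(2) * np.cos(2 * np.pi * t / n)  # exactly orthogonal pair
        x2 = np.sqrt(2) * np.sin(2 * np.pi * t / n)
        y = 0.8 * x1 - 0.3 * x2 + 0.1 * np.cos(4 * np.pi * t / n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        table = hierarchical_regression(df, [["x1", "x2"]], "y")
        for col in ("x1", "x2"):
            r = pearson_ci(df[col], y).r
            assert table.steps[0].terms.loc[col, "std_beta"] == pytest.approx(
                r, abs=1e-10
            )

    def test_toy_matches_normal_equations(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x2 = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        table = hierarchical_regression(df, [["x1"], ["x2"]], "y")
        # closed-form (XᵀX)⁻¹Xᵀy with intercept, computed independently
        X = np.column_stack([np.ones(6), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        step2 = table.steps[1]
        assert step2.terms.loc["x1", "beta"] == pytest.approx(beta[1], abs=1e-10)
        assert step2.terms.loc["x2", "beta"] == pytest.approx(beta[2], abs=1e-10)
        assert len(table.steps) == 2

    def test_adjusted_r2_not_above_r2(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "a": rng.normal(size=40),
                "b": rng.normal(size=40),
                "y": rng.normal(size=40),
            }
        )
        table = hierarchical_regression(df, [["a"], ["b"]], "y")
        for step in table.steps:
            assert step.adj_r2 <= step.r2 + 1e-12

    def test_collinear_terms_error(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": x + 1})
        with pytest.raises(ValueError, match="collinear"):
            hierarchical_regression(df, [["x", "x2"]], "y")

    def test_categorical_dummy_reference(self):
        df = pd.DataFrame(
            {
                "child_sex": ["male", "female"] * 10,
                "y": [1.0, 2.0] * 10,
            }
        )
        table = hierarchical_regression(df, [["child_sex"]], "y")
        # female is the reference; the male dummy carries the -1 contrast
        assert table.steps[0].terms.index[0] == "child_sex[male]"
        assert table.steps[0].terms.loc["child_sex[male]", "beta"] == pytest.approx(
            -1.0
        )

    def test_listwise_deletion_warns_with_count(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0],
                           "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        with pytest.warns(UserWarning, match="dropped 1 row"):
            table = hierarchical_regression(df, [["x"]], "y")
        assert table.steps[0].n == 5


class TestModeration:
    def test_deterministic_interaction_cancels_male_slope(self):
        """y = x for males, y = const for females: the interaction
        coefficient exactly offsets the male-stratum slope."""
        x = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        sex = ["female"] * 4 + ["male"] * 4
        y = np.array([5.0, 5.0, 5.0, 5.0, 1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"x": x, "child_sex": sex, "y": y})
        # the female stratum is constant: its correlation is undefined and
        # the probe is omitted with a warning
        with pytest.warns(UserWarning, match="female.*omitted"):
            res = moderation_analysis(df, "x", "y")
        step = res.regression.steps[-1]
        inter = res.regression.metadata["interaction_term"]
        # with female reference: exposure main effect = female slope = 0,
        # interaction = male slope - female slope = 1 (hand normal equations)
        assert step.terms.loc["x", "beta"] == pytest.approx(0.0, abs=1e-10)
        assert step.terms.loc[inter, "beta"] == pytest.approx(1.0, abs=1e-10)
        assert res.stratified["male"].r == pytest.approx(1.0)

    def test_stratified_correlations_match_generator_targets(self):
        df = simulate_cohort(CohortSimConfig(n_dyads=100_000, seed=21))
        res = moderation_analysis(
            df, "entropy_rate", "child_ec",
            covariates=["economic_satisfaction", "maternal_ec",
                        "maternal_sensitivity"],
        )
        assert res.stratified["male"].r == pytest.approx(-0.289, abs=0.03)
        assert res.stratified["female"].r == pytest.approx(-0.007, abs=0.03)

    def test_small_stratum_omitted_with_warning(self):
        df = pd.DataFrame(
            {
                "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
                "child_sex": ["male"] * 5 + ["female"] * 2,
                "y": [2.0, 1.0, 4.0, 3.0, 5.0, 1.0, 2.0],
            }
        )
        with pytest.warns(UserWarning, match="stratified correlation omitted"):
            res = moderation_analysis(df, "x", "y")
        assert "female" not in res.stratified
        assert "male" in res.stratified


class TestExtremeGroup:
    def test_identical_groups_give_zero_d(self):
        x = np.concatenate([np.arange(17.0), [100.0, 101.0, 102.0]])
        # low and high groups share the mean (2.0) exactly
        y = np.concatenate([[1.0, 2.0, 3.0] * 5, [2.0, 2.0], [1.0, 2.0, 3.0]])
        df = pd.DataFrame({"x": x, "y": y})
        res = extreme_group_analysis(df, "x", "y")
        assert res.comparison.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_toy_groups_match_textbook_formulas(self):
        """High group {4,5,6} vs rest {1,2,3}: hand-computed t, df, d."""
        df = pd.DataFrame({"x": np.arange(1.0, 7.0), "y": np.arange(1.0, 7.0)})
        res = extreme_group_analysis(df, "x", "y", high_quantile=0.5)
        c = res.comparison
        assert c.ns == (3, 3)
        assert c.means == (5.0, 2.0)
        # pooled sd = 1; t = 3 / sqrt(2/3); d = 3
        assert c.df == 4
        assert c.t == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert c.cohens_d == pytest.approx(3.0, abs=1e-12)
        assert np.sign(c.cohens_d) == np.sign(c.means[0] - c.means[1])

    def test_adjusted_model_and_low_dichotomization(self):
        df = simulate_cohort(CohortSimConfig(n_dyads=2_000, seed=17))
        res = extreme_group_analysis(
            df, "entropy_rate", "child_ec",
            covariates=["economic_satisfaction", "maternal_ec",
                        "maternal_sensitivity", "child_sex"],
            low_dichotomize=["maternal_sensitivity"],
            moderator="child_sex",
        )
        terms = res.adjusted_model.terms.index
        assert "entropy_rate[high]" in terms
        assert "maternal_sensitivity[low]" in terms
        assert "maternal_sensitivity" not in terms
        assert res.interaction_p is not None
        assert res.cutoffs.n_high == pytest.approx(0.15 * 2000, abs=25)

    def test_welch_flag_changes_df(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"x": np.arange(40.0), "y": rng.normal(size=40) * np.linspace(1, 3, 40)}
        )
        pooled = extreme_group_analysis(df, "x", "y")
        welch = extreme_group_analysis(df, "x", "y", welch=True)
        assert pooled.comparison.df == 38
        assert welch.comparison.df != 38

    def test_empty_high_group_error(self):
        df = pd.DataFrame({"x": [1.0] * 10, "y": np.arange(10.0)})
        with pytest.warns(UserWarning, match="identical"):
            with pytest.raises(ValueError, match="empty"):
                extreme_group_analysis(df, "x", "y")


@pytest.fixture(scope="module")
def study_results():
    df = simulate_cohort(CohortSimConfig(n_dyads=4_000, seed=33))
    return CohortStudy(df).fit()


class TestCohortStudy:

    def test_screening_recovers_generator_structure(self, study_results):
        included = set(study_results.screening.included)
        assert {"economic_satisfaction", "maternal_ec",
                "maternal_sensitivity"} <= included
        assert study_results.sex_screening.included == ["child_sex"]

    def test_summary_is_complete(self, study_results):
        text = study_results.summary()
        for needle in (
            "Covariate screening",
            "Hierarchical regression",
            "Stratified correlations",
            "Extreme-group contrast",
        ):
            assert needle in text

    def test_moderation_plot_renders(self, study_results, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        ax = study_results.plot_moderation()
        # one scatter + one fit line per sex stratum
        assert len(ax.lines) == 2
        ax.figure.savefig(tmp_path / "moderation.png")

    def test_pipeline_deterministic(self):
        df = simulate_cohort(CohortSimConfig(n_dyads=300, seed=5))
        a = CohortStudy(df).fit().summary()
        b = CohortStudy(df.copy()).fit().summary()
        assert a == b
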