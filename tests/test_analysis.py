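"""Statistical battery: rates, tests, logistic models, fits, sample size."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from steatodia import (
    CohortSpec,
    SeparationError,
    compare_groups,
    correlate,
    discordance_summary,
    generate_cohort,
    multivariable_logit,
    quad_fit,
    required_sample_size,
    simulate_discordance_outcome,
    stratified_comparison,
    univariable_logit,
    wilcoxon_paired_by_grade,
)


def _toy_cohort():
    # hand-enumerated: pairs (0,0),(0,1),(2,1),(3,1)
    return pd.DataFrame(
        {"hist_grade": [0, 0, 2, 3], "pdff_grade": [0, 1, 1, 1]}
    )


class TestDiscordanceSummary:
    def test_hand_enumerated_toy_cohort(self):
        s = discordance_summary(_toy_cohort())
        assert s.rate == pytest.approx(0.75)
        assert s.counts_by_direction["mri_over"] == 1
        assert s.counts_by_direction["mri_under"] == 2
        assert s.counts_by_magnitude.to_dict() == {1: 2, 2: 1}
        assert s.crosstab.to_numpy().sum() == 4
        assert s.crosstab.loc[3, 1] == 1

    def test_identical_grades_give_diagonal_crosstab(self):
        df = pd.DataFrame({"hist_grade": [0, 1, 2, 3, 2], "pdff_grade": [0, 1, 2, 3, 2]})
        s = discordance_summary(df)
        assert s.rate == 0.0
        off_diag = s.crosstab.to_numpy() - np.diag(np.diag(s.crosstab.to_numpy()))
        assert off_diag.sum() == 0

    def test_crosstab_marginals_match_grade_distributions(self, graded_cohort):
        s = discordance_summary(graded_cohort)
        np.testing.assert_array_equal(
            s.crosstab.sum(axis=1).to_numpy(),
            graded_cohort.hist_grade.value_counts().reindex(range(4), fill_value=0).to_numpy(),
        )
        np.testing.assert_array_equal(
            s.crosstab.sum(axis=0).to_numpy(),
            graded_cohort.pdff_grade.value_counts().reindex(range(4), fill_value=0).to_numpy(),
        )
        lo, hi = s.rate_ci
        assert lo < s.rate < hi

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            discordance_summary(pd.DataFrame({"hist_grade": [], "pdff_grade": []}))


class TestCompareGroups:
    def test_duplicated_data_gives_large_p(self):
        base = np.arange(30, dtype=float)
        df = pd.DataFrame({"g": [0] * 30 + [1] * 30, "x": np.tile(base, 2)})
        res = compare_groups(df, "g", "x", test="t")
        assert res.p_value > 0.5

    def test_fisher_toy_table_matches_hypergeometric(self):
        # 2x2 table (10,0 / 0,10): exact p = 2 / C(20,10)
        df = pd.DataFrame({"g": [0] * 10 + [1] * 10, "x": [0] * 10 + [1] * 10})
        res = compare_groups(df, "g", "x", test="fisher")
        assert res.p_value == pytest.approx(2 / 184756, rel=1e-9)
        assert res.p_value < 0.001

    def test_auto_switches_to_mannwhitney_for_skewed_data(self, rng):
        df = pd.DataFrame(
            {"g": [0] * 100 + [1] * 100, "x": rng.lognormal(0, 1.5, 200)}
        )
        res = compare_groups(df, "g", "x", test="auto")
        assert res.test_used == "mannwhitney"

    def test_planted_stratum_difference_detected(self, rng):
        # S0 patients: discordant subgroup gets systematically higher tiny area
        n = 120
        disc = np.repeat([0, 1], n // 2)
        tiny = rng.normal(2.7, 1.8, n) + 3.0 * disc
        df = pd.DataFrame({"hist_grade": 0, "discordant": disc, "tiny_pct": tiny})
        table = stratified_comparison(df, ["tiny_pct"])
        row = table[(table.stratum == 0) & (table.variable == "tiny_pct")].iloc[0]
        assert row.p_value < 0.01
        assert row.mean_g1 > row.mean_g0

    def test_degenerate_group_raises(self):
        df = pd.DataFrame({"g": [0, 0, 0, 1], "x": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            compare_groups(df, "g", "x", test="t")


class TestUnivariableLogit:
    def test_independent_predictor_gives_unit_or(self, rng):
        n = 4000
        df = pd.DataFrame(
            {"discordant": rng.integers(0, 2, n), "x": rng.normal(0, 1, n)}
        )
        res = univariable_logit(df, "x")
        row = res.table.iloc[0]
        assert row.ci_low < 1.0 < row.ci_high
        assert row.odds_ratio == pytest.approx(1.0, abs=0.15)

    def test_planted_slope_recovered_within_ci(self, rng):
        n, beta = 2000, 0.25
        x = rng.normal(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + beta * x)))).astype(int)
        res = univariable_logit(pd.DataFrame({"discordant": y, "x": x}), "x")
        row = res.table.iloc[0]
        assert row.ci_low <= np.exp(beta) <= row.ci_high

    def test_binary_predictor_equals_cross_product_ratio(self):
        df = pd.DataFrame(
            {"discordant": [0] * 60 + [1] * 40, "x": [0] * 45 + [1] * 15 + [0] * 12 + [1] * 28}
        )
        a = ((df.x == 1) & (df.discordant == 1)).sum()
        b = ((df.x == 1) & (df.discordant == 0)).sum()
        c = ((df.x == 0) & (df.discordant == 1)).sum()
        d = ((df.x == 0) & (df.discordant == 0)).sum()
        res = univariable_logit(df, "x")
        assert res.table.odds_ratio.iloc[0] == pytest.approx(a * d / (b * c), abs=1e-6)

    @pytest.mark.filterwarnings("ignore::UserWarning", "ignore::RuntimeWarning")
    def test_complete_separation_is_flagged(self):
        df = pd.DataFrame({"discordant": [0] * 20 + [1] * 20,
                           "x": list(range(20)) + list(range(30, 50))})
        with pytest.raises(SeparationError):
            univariable_logit(df, "x")

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"discordant": [1] * 10, "x": np.arange(10.0)})
        with pytest.raises(ValueError):
            univariable_logit(df, "x")


@pytest.fixture(scope="module")
def planted_cohort():
    cohort = generate_cohort(CohortSpec(seed=77))
    cohort["discordant"] = simulate_discordance_outcome(
        cohort,
        {"tiny_pct": 0.30, "small_pct": 0.90, "large_pct": -0.10},
        intercept=-2.0,
        seed=78,
    )
    return cohort


class TestMultivariableLogit:
    def test_planted_directions_recovered(self, planted_cohort):
        res = multivariable_logit(
            planted_cohort, ["tiny_pct", "small_pct", "large_pct", "total_pct"]
        )
        t = res.table
        assert t.loc["tiny_pct", "odds_ratio"] > 1
        assert t.loc["small_pct", "odds_ratio"] > 1
        assert t.loc["large_pct", "odds_ratio"] < 1
        assert (t.ci_low <= t.odds_ratio).all() and (t.odds_ratio <= t.ci_high).all()

    def test_sum_variable_excluded_for_collinearity(self, planted_cohort):
        res = multivariable_logit(
            planted_cohort, ["tiny_pct", "small_pct", "large_pct", "total_pct"]
        )
        assert "total_pct" in res.predictors_excluded_collinear
        assert "total_pct" not in res.predictors_entered
        assert not set(res.predictors_excluded_collinear) & set(res.predictors_entered)

    def test_forced_only_model_when_no_candidate_passes(self, rng):
        n = 500
        df = pd.DataFrame(
            {
                "discordant": rng.integers(0, 2, n),
                "age": rng.normal(55, 10, n),
                "sex": rng.choice(["female", "male"], n),
                "z1": rng.normal(0, 1, n),
                "z2": rng.normal(0, 1, n),
            }
        )
        res = multivariable_logit(df, ["z1", "z2"])
        assert res.predictors_entered == ["age", "sex"]

    def test_pairwise_screen_drops_duplicated_predictor(self, rng):
        n = 800
        x = rng.normal(0, 2, n)
        x_dup = x + rng.normal(0, 0.1, n)  # |r| > 0.99 with x
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * x))).astype(int)
        df = pd.DataFrame(
            {"discordant": y, "age": rng.normal(55, 10, n),
             "sex": rng.choice(["female", "male"], n), "x": x, "x_dup": x_dup}
        )
        res = multivariable_logit(df, ["x", "x_dup"])
        assert len(set(res.predictors_entered) & {"x", "x_dup"}) == 1
        assert len(res.predictors_excluded_collinear) == 1

    def test_interaction_term_reported(self, planted_cohort):
        res = multivariable_logit(
            planted_cohort,
            ["tiny_pct", "large_pct"],
            interactions=[("fibrosis_f2_4", "large_pct")],
        )
        assert "fibrosis_f2_4:large_pct" in res.table.index


class TestCorrelate:
    def test_exact_linear_gives_pearson_one(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df.x + 1
        assert correlate(df, "x", "y", "pearson").coefficient == pytest.approx(1.0)

    def test_reversed_ranks_give_spearman_minus_one(self):
        df = pd.DataFrame({"x": np.arange(20.0), "y": -np.arange(20.0) ** 3})
        assert correlate(df, "x", "y", "spearman").coefficient == pytest.approx(-1.0)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x = rng.lognormal(0, 1, 50)
        df = pd.DataFrame({"x": x, "y": np.log(x) ** 3 + np.exp(np.log(x))})
        assert correlate(df, "x", "y", "spearman").coefficient == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            correlate(df, "x", "y", "pearson")


class TestWilcoxonByGrade:
    def test_identical_pairs_reported_degenerate(self):
        df = pd.DataFrame(
            {"hist_grade": [0] * 10, "pdff_pct": np.arange(10.0), "total_pct": np.arange(10.0)}
        )
        out = wilcoxon_paired_by_grade(df)
        assert out.iloc[0].status == "degenerate"
        assert out.iloc[0].p_value == 1.0

    def test_planted_shift_detected(self, rng):
        n = 50
        total = rng.normal(10, 3, n)
        df = pd.DataFrame(
            {"hist_grade": [1] * n, "total_pct": total,
             "pdff_pct": total + 2.0 + rng.normal(0, 0.8, n)}
        )
        out = wilcoxon_paired_by_grade(df)
        assert out.iloc[0].p_value < 0.01

    def test_null_differences_rarely_significant(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            total = r.normal(10, 3, 200)
            df = pd.DataFrame(
                {"hist_grade": [0] * 200, "total_pct": total,
                 "pdff_pct": total + r.normal(0, 1, 200)}
            )
            hits += wilcoxon_paired_by_grade(df).iloc[0].p_value > 0.01
        assert hits >= int(0.95 * n_seeds)

    def test_small_stratum_flagged(self):
        df = pd.DataFrame(
            {"hist_grade": [2] * 3, "pdff_pct": [1.0, 2.0, 3.0], "total_pct": [2.0, 1.0, 4.0]}
        )
        out = wilcoxon_paired_by_grade(df)
        assert out.iloc[0].status == "too_small"
        assert np.isnan(out.iloc[0].p_value)


class TestQuadFit:
    def test_exact_parabola(self):
        x = np.linspace(-3, 3, 20)
        res = quad_fit(x, x**2)
        assert res.coefficients[0] == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)
        assert res.concavity == "up"

    def test_constant_y_has_no_curvature(self):
        res = quad_fit(np.linspace(0, 10, 10), np.full(10, 3.0))
        assert res.coefficients[0] == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == 0.0
        assert res.concavity == "none"

    def test_composition_concavities_from_generator(self):
        cohort = generate_cohort(CohortSpec(n_patients=2000, seed=4))
        up = quad_fit(cohort.total_pct, cohort.large_pct)
        down = quad_fit(cohort.total_pct, cohort.tiny_pct + cohort.small_pct)
        assert up.concavity == "up"
        assert down.concavity == "down"
        assert up.r_squared > 0.8

    def test_rank_deficient_x_rejected(self):
        with pytest.raises(ValueError):
            quad_fit([1.0, 1.0, 2.0, 2.0], [0.0, 0.0, 1.0, 1.0])


class TestRequiredSampleSize:
    @pytest.mark.parametrize(
        "p,d,alpha,expected",
        [
            (0.6, 0.05, 0.05, 369),
            (0.5, 0.05, 0.05, 385),  # 1.95996^2 * 0.25 / 0.0025 = 384.15
            (0.6, 0.10, 0.05, 93),   # 368.79 / 4 = 92.2
        ],
    )
    def test_worked_values(self, p, d, alpha, expected):
        assert required_sample_size(p, d, alpha) == expected

    def test_decreasing_in_precision(self):
        sizes = [required_sample_size(0.6, d, 0.05) for d in (0.02, 0.05, 0.1, 0.2)]
        assert sizes == sorted(sizes, reverse=True)

    def test_maximal_at_half_prevalence(self):
        at_half = required_sample_size(0.5, 0.05, 0.05)
        for p in (0.1, 0.3, 0.6, 0.9):
            assert required_sample_size(p, 0.05, 0.05) <= at_half

    @pytest.mark.parametrize("bad", [dict(prevalence=0.0), dict(precision_d=1.0), dict(alpha=0.0)])
    def test_arguments_validated(self, bad):
        kwargs = dict(prevalence=0.6, precision_d=0.05, alpha=0.05)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            required_sample_size(**kwargs)
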