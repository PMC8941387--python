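"""Group statistics: screening, ANCOVA, effect sizes, densities."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from facemasc.stats import (ancova_test, bonferroni_alpha,
                            classify_diagnosis, comparison_table,
                            density_report, screen_covariates)
from facemasc.synthetic import (CELLS, FeatureTableConfig,
                                generate_feature_table)

VARS10 = FeatureTableConfig().distance_variables


class TestScreenCovariates:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        cov = rng.normal(size=50)
        table = pd.DataFrame({"v": 2 * cov, "age": cov,
                              "facial_area": rng.normal(size=50)})
        res = screen_covariates(table, ["v"])
        by_cov = {r.covariate: r for r in res}
        assert by_cov["age"].pearson_r == pytest.approx(1.0)
        assert by_cov["age"].include

    def test_zero_variance_errors(self):
        table = pd.DataFrame({"v": [1.0] * 10, "age": range(10),
                              "facial_area": range(10)})
        with pytest.raises(ValueError, match="zero-variance"):
            screen_covariates(table, ["v"])

    def test_too_few_cases(self):
        table = pd.DataFrame({"v": [1.0, 2.0], "age": [3.0, 4.0],
                              "facial_area": [5.0, 6.0]})
        with pytest.raises(ValueError, match="3 complete"):
            screen_covariates(table, ["v"])

    def test_null_false_positive_rate(self):
        """Independent pairs reject at ~5%: fraction with p < 0.05 inside
        the binomial 99% band for 1000 replicates."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(1000):
            x = rng.normal(size=355)
            y = rng.normal(size=355)
            table = pd.DataFrame({"v": x, "age": y,
                                  "facial_area": np.arange(355.0)})
            r = [s for s in screen_covariates(table, ["v"])
                 if s.covariate == "age"][0]
            hits += r.p_value < 0.05
        assert 32 <= hits <= 68

    def test_calibrated_cohort_correlations_in_published_band(self):
        """Age/area correlations with the ten distances stay inside the
        0.12-0.56 band reported for real cohorts, for >= 90% of seeds."""
        good = 0
        n_seeds = 25
        for seed in range(n_seeds):
            table, _ = generate_feature_table(seed=seed)
            res = screen_covariates(table, VARS10)
            rs = [r.pearson_r for r in res]
            good += all(0.12 <= r <= 0.56 for r in rs)
        assert good >= 0.9 * n_seeds


class TestBonferroni:
    @pytest.mark.parametrize("m, rate, expected", [
        (10, 0.05, 0.005),
        (1, 0.05, 0.05),
        (20, 0.05, 0.0025),
    ])
    def test_arithmetic(self, m, rate, expected):
        assert bonferroni_alpha(m, rate) == expected

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


class TestAncova:
    def test_denominator_df_355_subjects(self, feature_table):
        res = ancova_test(feature_table, "masculinity_score")
        assert res.df_group == (1, 349)
        assert res.n == 355
        assert res.F_group >= 0
        assert res.significant == (res.p_group < res.alpha)

    def test_without_covariates_matches_plain_two_way_anova(
            self, feature_table):
        """Dropping the covariates reproduces the factorial ANOVA."""
        res = ancova_test(feature_table, "e_nose_width", covariates=())
        model = smf.ols(
            "e_nose_width ~ C(family_group, Sum) * C(sex, Sum)",
            data=feature_table).fit()
        aov = anova_lm(model, typ=3)
        assert res.F_group == pytest.approx(
            float(aov.loc["C(family_group, Sum)", "F"]), abs=1e-8)
        assert res.df_group == (1, 351)

    def test_positive_d_when_autism_cells_larger(self):
        cfg = FeatureTableConfig().with_group_effect(
            "e_nasal_bridge_length", 0.5)
        table, _ = generate_feature_table(cfg, seed=0)
        res = ancova_test(table, "e_nasal_bridge_length")
        assert res.d_adjusted > 0
        assert res.d_ci95[0] < res.d_adjusted < res.d_ci95[1]

    def test_sex_effect_is_large_and_male_positive(self, feature_table):
        res = ancova_test(feature_table, "g_forehead_width")
        assert res.d_sex > 0.5
        assert res.p_sex < 1e-10

    def test_empty_cell_errors(self, feature_table):
        broken = feature_table[
            ~((feature_table.sex == "male")
              & (feature_table.family_group == "autism_parent"))]
        with pytest.raises(ValueError, match="cell"):
            ancova_test(broken, "masculinity_score")

    def test_constant_covariate_errors(self, feature_table):
        table = feature_table.copy()
        table["age"] = 40.0
        with pytest.raises(ValueError, match="age"):
            ancova_test(table, "masculinity_score")

    def test_comparison_table_layout(self, feature_table):
        res = [ancova_test(feature_table, v)
               for v in ("masculinity_score", "e_nose_width")]
        out = comparison_table(res, feature_table)
        assert list(out["variable"]) == ["masculinity_score", "e_nose_width"]
        for col in ("F", "p", "d", "d_ci_low", "d_ci_high", "significant"):
            assert col in out.columns
        assert out["M_autism_parent_male"].iloc[0] > \
            out["M_autism_parent_female"].iloc[0]


class TestClassifyDiagnosis:
    def test_permuted_groups_at_chance(self, feature_table):
        """Shuffling family labels leaves balanced accuracy at chance."""
        accs = []
        table = feature_table.copy()
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            table["family_group"] = rng.permutation(
                table["family_group"].to_numpy())
            accs.append(classify_diagnosis(
                table, ["masculinity_score"] + VARS10[:6],
                seed=seed, balance=True))
        assert 0.45 <= np.mean(accs) <= 0.55

    def test_signal_increases_accuracy(self):
        """Doubling the group masculinization raises mean accuracy."""
        accs = {0.25: [], 0.5: []}
        for d in accs:
            cfg = FeatureTableConfig().with_group_effect(
                "g_forehead_width", d)
            for seed in range(15):
                table, _ = generate_feature_table(cfg, seed=seed)
                accs[d].append(classify_diagnosis(
                    table, ["g_forehead_width"], seed=seed, balance=True))
        assert np.mean(accs[0.5]) > np.mean(accs[0.25])


class TestDensityReport:
    def test_densities_normalised(self, feature_table):
        cells = density_report(feature_table)
        assert len(cells) == 4
        for c in cells:
            assert np.all(c.density >= 0)
            mass = np.trapezoid(c.density, c.grid)
            assert mass == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_cell_concentrates(self):
        rows = []
        for grp in ("autism_parent", "comparison_parent"):
            for sex in ("male", "female"):
                for _ in range(5):
                    rows.append({"family_group": grp, "sex": sex,
                                 "masculinity_score": 0.5})
        cells = density_report(pd.DataFrame(rows))
        for c in cells:
            inside = (c.grid >= 0.48) & (c.grid <= 0.52)
            mass = np.trapezoid(c.density[inside], c.grid[inside])
            assert mass >= 0.99

    def test_small_cell_errors(self, feature_table):
        tiny = feature_table.groupby(
            ["family_group", "sex"], observed=True).head(3)
        with pytest.raises(ValueError, match=">= 5"):
            density_report(tiny)
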