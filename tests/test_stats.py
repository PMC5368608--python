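"""Statistics: ANOVA/Tukey mean squares, ICC, CV, Bland-Altman, regression.

Independent oracles: hand-worked sums of squares for a small repeated table,
pingouin for the RM-ANOVA and ICC, closed-form least squares, Monte Carlo
for the agreement statistics.
"""

import numpy as np
import pandas as pd
import pytest

from cinestrain.stats import (
    bland_altman,
    compare_groups,
    cv_agreement,
    fit_linear_models,
    icc,
    rm_anova,
    tukey_rm,
)

# 3x3 repeated table with hand-workable sums of squares:
# grand mean 31/9; SS_cond = SS_subj = 1098/81; SS_total = 254/9;
# SS_err = 90/81; F = (1098/162) / (90/324) = 24.4 on (2, 4) df.
HAND_TABLE = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0], [3.0, 5.0, 7.0]])


class TestRepeatedAnova:
    def test_hand_worked_sums_of_squares(self):
        F, (dfc, dfe), p = rm_anova(HAND_TABLE)
        assert (dfc, dfe) == (2, 4)
        assert F == pytest.approx(24.4, abs=1e-9)
        from scipy.stats import f as fdist
        assert p == pytest.approx(fdist.sf(24.4, 2, 4), abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.normal(0, 1, (12, 3)) + np.array([0.0, 0.4, 0.9])
        F, _, p = rm_anova(data)
        long = pd.DataFrame({
            "s": np.repeat(np.arange(12), 3),
            "c": np.tile(["a", "b", "c"], 12),
            "y": data.ravel(),
        })
        aov = pg.rm_anova(data=long, dv="y", within="c", subject="s")
        assert F == pytest.approx(float(aov.loc[0, "F"]), rel=1e-9)
        assert p == pytest.approx(float(aov.loc[0, "p_unc"]), rel=1e-9)

    def test_vectorized_over_replicates(self, rng):
        data = rng.normal(0, 1, (50, 10, 3))
        F_batch, _, p_batch = rm_anova(data)
        for i in (0, 17, 49):
            F_i, _, p_i = rm_anova(data[i])
            assert F_batch[i] == pytest.approx(F_i)
            assert p_batch[i] == pytest.approx(p_i)

    def test_type_one_error_under_exchangeable_null(self, rng):
        """Rejection rate at alpha = 0.05 stays within 0.05 +/- 0.01 when the
        three conditions are exchangeable (5,000 replicates, n = 130)."""
        reps, n, k, rho = 5000, 130, 3, 0.6
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)
        data = rng.standard_normal((reps, n, k)) @ chol.T
        _, _, p = rm_anova(data)
        rate = float(np.mean(p < 0.05))
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_unbalanced_design_rejected(self):
        bad = HAND_TABLE.copy()
        bad[1, 2] = np.nan
        with pytest.raises(ValueError, match="unbalanced|missing"):
            rm_anova(bad)


class TestTukey:
    def test_pairwise_pvalues_ordered_by_separation(self, rng):
        data = rng.normal(0, 1, (15, 3)) + np.array([0.0, 0.5, 3.0])
        p = tukey_rm(data, ["a", "b", "c"])
        assert p[("a", "c")] < p[("a", "b")]
        assert all(0 <= v <= 1 for v in p.values())

    def test_distant_means_reject(self, rng):
        data = rng.normal(0, 0.5, (20, 3)) + np.array([0.0, 5.0, 10.0])
        p = tukey_rm(data)
        assert max(p.values()) < 1e-4


class TestCompareGroups:
    def test_identical_groups_give_t_zero(self, rng):
        g = rng.normal(0, 1, 20)
        res = compare_groups([g, g.copy()], design="independent")
        assert res.test == "independent t-test"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0, abs=1e-12)

    def test_repeated_normal_branch_runs_anova_with_posthoc(self, rng):
        data = rng.normal(0, 1, (20, 3)) + np.array([0.0, 1.0, 2.0])
        res = compare_groups(data, design="repeated", labels=["endo", "mid", "epi"])
        assert res.test == "repeated-measures ANOVA"
        assert res.normal is True
        assert ("endo", "epi") in res.posthoc

    def test_repeated_non_normal_branch_uses_friedman(self, rng):
        data = rng.exponential(1.0, (40, 3)) ** 3
        res = compare_groups(data, design="repeated")
        assert res.test == "Friedman"
        assert res.normal is False

    def test_simulated_cohort_layer_difference_rejects(self):
        from cinestrain import simulate_cohort

        df = simulate_cohort(seed=42)
        data = df[["Ecc_endo", "Ecc_mid", "Ecc_epi"]].to_numpy()
        res = compare_groups(data, design="repeated", labels=["endo", "mid", "epi"])
        assert res.pvalue < 0.001
        assert all(p < 0.001 for p in res.posthoc.values())

    def test_missing_condition_is_an_error(self):
        data = np.array([[1.0, np.nan], [2.0, 3.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="unbalanced|missing"):
            compare_groups(data, design="repeated")


class TestRegression:
    def test_exact_linear_relationship(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df.x
        fit = fit_linear_models(df, "y", ["x"])
        assert fit.loc[0, "r"] == pytest.approx(1.0)
        assert fit.loc[0, "slope"] == pytest.approx(2.0)

    def test_slope_matches_closed_form_on_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.1, 5.9, 8.2, 9.9])
        fit = fit_linear_models(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        closed = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit.loc[0, "slope"] == pytest.approx(closed, rel=1e-12)

    def test_collinear_predictors_named(self, rng):
        x = rng.normal(0, 1, 30)
        df = pd.DataFrame({"a": x, "b": 2 * x, "y": x + rng.normal(0, 1, 30)})
        with pytest.raises(ValueError, match="a, b"):
            fit_linear_models(df, "y", ["a", "b"])

    def test_constant_predictor_rejected(self, rng):
        df = pd.DataFrame({"a": np.ones(20), "y": rng.normal(0, 1, 20)})
        with pytest.raises(ValueError, match="constant"):
            fit_linear_models(df, "y", ["a"])


class TestAgreement:
    def test_duplicated_measurements_are_perfect(self, rng):
        x = rng.normal(20, 4, 12)
        pairs = np.column_stack([x, x])
        assert icc(pairs) == pytest.approx(1.0)
        assert cv_agreement(pairs) == 0.0
        res = bland_altman(pairs)
        assert res.bias == 0.0 and res.sd_diff == 0.0

    def test_large_rater_offset_kills_absolute_agreement(self, rng):
        x = rng.normal(0, 1, 30)
        pairs = np.column_stack([x, x + 50.0])
        assert icc(pairs) < 0.05

    def test_icc_matches_pingouin_on_worked_table(self, rng):
        pg = pytest.importorskip("pingouin")
        arr = rng.normal(10, 2, (6, 1)) + rng.normal(0, 0.7, (6, 2))
        long = pd.DataFrame({
            "t": np.repeat(np.arange(6), 2),
            "r": np.tile(["r1", "r2"], 6),
            "y": arr.ravel(),
        })
        tab = pg.intraclass_corr(data=long, targets="t", raters="r", ratings="y")
        expected = float(tab.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert icc(arr) == pytest.approx(expected, abs=1e-9)

    def test_constant_offset_has_zero_cv(self):
        pairs = np.array([[11.0, 10.0], [21.0, 20.0], [31.0, 30.0]])
        assert cv_agreement(pairs) == pytest.approx(0.0, abs=1e-12)
        res = bland_altman(pairs)
        assert res.bias == pytest.approx(1.0)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_cv_recovers_known_noise_level(self, rng):
        truth = rng.normal(100, 10, 1000)
        noise = 3.0  # 3% of the grand mean
        pairs = np.column_stack([
            truth + rng.normal(0, noise, 1000), truth + rng.normal(0, noise, 1000)
        ])
        assert cv_agreement(pairs) == pytest.approx(3.0, abs=0.5)

    def test_bland_altman_monte_carlo(self, rng):
        first = rng.normal(0, 3, 10_000)
        second = first - rng.normal(0.2, 1.0, 10_000)
        res = bland_altman(np.column_stack([first, second]))
        assert res.bias == pytest.approx(0.2, abs=0.03)
        assert res.loa_lower == pytest.approx(-1.76, abs=0.05)
        assert res.loa_upper == pytest.approx(2.16, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc(np.full((6, 2), 3.0))
        with pytest.raises(ValueError, match="zero"):
            cv_agreement(np.zeros((6, 2)))
        with pytest.raises(ValueError):
            icc(np.ones((3, 2)) * np.arange(3)[:, None])  # n < 5
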