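"""Partial correlation, group tests, stepwise regression, cohort report."""

import numpy as np
import pandas as pd
import pytest

from lcsync import response, stats, synthetic


class TestPartialCorrelation:
    def test_identity_without_covariates(self):
        x = np.arange(10.0)
        res = stats.partial_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.df == 8

    def test_equals_plain_pearson_with_empty_covariates(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = stats.partial_correlation(x, y)
        expected = np.corrcoef(x, y)[0, 1]
        assert res.r == pytest.approx(expected, abs=1e-12)

    def test_fully_explained_by_covariates(self):
        rng = np.random.default_rng(1)
        n = 400
        cov = rng.normal(size=(n, 2))
        y = cov @ np.array([1.5, -0.7]) + 2.0
        x = rng.normal(size=n)
        # exact linear functions leave degenerate residuals; a whisper of noise
        # leaves only chance-level correlation (SD ~ 1/sqrt(n))
        res = stats.partial_correlation(x, y + 1e-6 * rng.normal(size=n), cov)
        assert abs(res.r) < 0.2

    def test_df_accounts_for_covariates(self):
        rng = np.random.default_rng(2)
        res = stats.partial_correlation(
            rng.normal(size=40), rng.normal(size=40), rng.normal(size=(40, 3))
        )
        assert res.df == 40 - 2 - 3

    def test_invariant_under_affine_covariate_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=50), rng.normal(size=50)
        cov = rng.normal(size=(50, 3))
        transform = np.array([[2.0, 0.3, 0.0], [0.0, -1.0, 0.5], [1.0, 0.0, 4.0]])
        base = stats.partial_correlation(x, y, cov)
        mapped = stats.partial_correlation(x, y, cov @ transform + 7.0)
        assert mapped.r == pytest.approx(base.r, abs=1e-10)
        assert mapped.p == pytest.approx(base.p, abs=1e-10)

    def test_collinear_covariates_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        base = rng.normal(size=(40, 2))
        cov = np.column_stack([base, base.sum(axis=1)])
        with pytest.warns(UserWarning, match="collinear"):
            res = stats.partial_correlation(x, y, cov)
        ref = stats.partial_correlation(x, y, base)
        assert res.r == pytest.approx(ref.r, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        cohort = response.add_response_columns(synthetic.gen_cohort(synthetic.CohortParams(seed=7)))
        mine = stats.partial_correlation(
            cohort["cnr_lc"], cohort["rate_updrs"], cohort[["age", "duration_med", "ledd"]]
        )
        ref = pg.partial_corr(
            cohort, x="cnr_lc", y="rate_updrs", covar=["age", "duration_med", "ledd"]
        )
        assert mine.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert mine.p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats.partial_correlation(np.ones(10), np.arange(10.0))

    def test_monte_carlo_recovery_and_scatter(self):
        rs = []
        for seed in range(300):
            cohort = response.add_response_columns(
                synthetic.gen_cohort(synthetic.CohortParams(target_r=0.42, seed=seed))
            )
            rs.append(
                stats.partial_correlation(
                    cohort["cnr_lc"], cohort["rate_updrs"], cohort[["age", "duration_med", "ledd"]]
                ).r
            )
        assert abs(np.mean(rs) - 0.42) < 0.025
        # single-replicate scatter approx (1 - r^2)/sqrt(n) ~ 0.11 at n = 57
        assert 0.07 < np.std(rs) < 0.16


class TestTwoSampleT:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0]
        t, p = stats.two_sample_t(a, a)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swapping_groups_negates_t(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        t_ab, p_ab = stats.two_sample_t(a, b)
        t_ba, p_ba = stats.two_sample_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_matches_pooled_formula_hand_computation(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([3.0, 5.0, 6.0])
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        t, _ = stats.two_sample_t(a, b)
        assert t == pytest.approx(expected_t, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.two_sample_t([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            stats.two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestChiSquare:
    def test_proportional_table(self):
        stat, p = stats.chi_square_2x2(np.array([[10, 10], [20, 20]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        # expected cells all 12.5; sum (O-E)^2/E = 4 * 7.5^2 / 12.5 = 18
        stat, _ = stats.chi_square_2x2(np.array([[20, 5], [5, 20]]))
        assert stat == pytest.approx(18.0)

    def test_transposition_invariance(self):
        table = np.array([[12, 7], [9, 15]])
        assert stats.chi_square_2x2(table)[0] == pytest.approx(stats.chi_square_2x2(table.T)[0])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            stats.chi_square_2x2(np.array([[0, 0], [5, 10]]))


def make_candidates(rng, n, names=("x1", "x2", "x3", "x4", "x5")):
    return pd.DataFrame({nm: rng.normal(size=n) for nm in names})


class TestStepwiseRegression:
    def test_planted_predictor_selected(self):
        # the planted effect always enters; a null co-entry happens at roughly
        # the 1 - (1 - p_enter)^4 ~ 19% family rate, so exact selection of
        # {x1} holds in about 81% of replicates
        planted, exact = 0, 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = make_candidates(rng, 200)
            y = 0.4 * x["x1"].to_numpy() + rng.normal(size=200)
            res = stats.stepwise_regression(y, x)
            planted += "x1" in res.selected
            exact += res.selected == ["x1"]
        assert planted / reps >= 0.95
        assert exact / reps > 0.5
        assert abs(exact / reps - 0.95**4) < 0.15

    def test_null_candidates_entry_rate(self):
        entered = 0
        reps = 300
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            x = make_candidates(rng, 120)
            y = rng.normal(size=120)
            entered += len(stats.stepwise_regression(y, x).selected) > 0
        # P(any of 5 independent tests < .05) = 1 - .95^5 ~ 0.226
        expected = 1 - 0.95**5
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(entered / reps - expected) < 4 * se + 0.02

    def test_orthogonal_dominant_effect_matches_full_ols(self):
        rng = np.random.default_rng(5)
        n = 256
        t = np.arange(n)
        # orthogonal design: distinct Fourier columns
        x = pd.DataFrame(
            {f"x{k}": np.sqrt(2) * np.cos(2 * np.pi * (k + 1) * t / n) for k in range(4)}
        )
        y = 5.0 * x["x1"].to_numpy() + 0.05 * rng.normal(size=n)
        res = stats.stepwise_regression(y, x)
        assert "x1" in res.selected
        ys = (y - y.mean()) / y.std(ddof=0)
        full = np.linalg.lstsq(
            np.column_stack([np.ones(n)] + [(x[c] - x[c].mean()) / x[c].std(ddof=0) for c in x]),
            ys,
            rcond=None,
        )[0]
        assert res.betas["x1"] == pytest.approx(full[2], abs=1e-8)  # x1 is column 2

    def test_thresholds_of_one_reduce_to_full_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        x = make_candidates(rng, 80)
        y = rng.normal(size=80) + 0.3 * x["x2"].to_numpy()
        res = stats.stepwise_regression(y, x, p_enter=1.0, p_remove=1.0)
        assert set(res.selected) == set(x.columns)
        xs = (x - x.mean()) / x.std(ddof=0)
        ys = (y - y.mean()) / y.std(ddof=0)
        fit = sm.OLS(ys, sm.add_constant(xs)).fit()
        for nm in x.columns:
            assert res.betas[nm] == pytest.approx(fit.params[nm], abs=1e-9)
            assert res.p_values[nm] == pytest.approx(fit.pvalues[nm], abs=1e-9)

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(7)
        x = make_candidates(rng, 6)
        with pytest.raises(ValueError):
            stats.stepwise_regression(rng.normal(size=6), x)


class TestCohortAnalysis:
    def test_global_null_cohort(self):
        params = synthetic.CohortParams(target_r=0.0, target_r_sync=0.0, seed=21)
        params.covariate_effects = {k: (0.0, 0.0, 0.0) for k in params.covariate_effects}
        report = stats.run_cohort_analysis(synthetic.gen_cohort(params))
        rs = [abs(c["r"]) for c in report["correlations"].values()]
        assert np.mean(rs) < 0.25

    def test_planted_lc_effect_selected_over_sn(self):
        selected = []
        for seed in range(40):
            report = stats.run_cohort_analysis(
                synthetic.gen_cohort(synthetic.CohortParams(seed=seed))
            )
            selected.append(report["stepwise"]["selected"])
        lc_picked = sum("cnr_lc" in s for s in selected)
        sn_picked = sum("cnr_sn" in s for s in selected)
        assert lc_picked > 20  # majority of replicates
        assert sn_picked < lc_picked

    def test_report_deterministic(self):
        cohort = synthetic.gen_cohort(synthetic.CohortParams(seed=2))
        assert stats.run_cohort_analysis(cohort) == stats.run_cohort_analysis(cohort)

    def test_group_sizes_at_reference_n(self):
        report = stats.run_cohort_analysis(synthetic.gen_cohort(synthetic.CohortParams(seed=0)))
        assert report["group_sizes"] == {"response": 29, "resistance": 28}

    def test_missing_columns_named(self):
        cohort = synthetic.gen_cohort(synthetic.CohortParams(seed=0)).drop(columns=["ledd", "sex"])
        with pytest.raises(ValueError, match="ledd"):
            stats.run_cohort_analysis(cohort)
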