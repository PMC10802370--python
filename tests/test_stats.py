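"""Mixed-model estimation, multiplicity control, and regression analyses."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from infantfc.simulate import CohortSpec, GrowthModel, simulate_cohort
from infantfc.stats import (bonferroni_threshold, fc_outcome_regression, fdr_bh,
                            fit_fc_age_lmm, growth_fc_regression)

CONN = "L-front|R-front"


def _clean_spec(**kw):
    base = dict(n_subjects=80, fixed_effects={}, chromophores=("HbO2",),
                growth_model=GrowthModel(fc_slopes={}), seed=0)
    base.update(kw)
    return CohortSpec(**base)


class TestBonferroni:
    def test_printed_threshold_for_21_tests(self):
        assert bonferroni_threshold(0.05, 21) == pytest.approx(0.00238, abs=5e-6)

    def test_single_test_unchanged(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_fifteen_tests(self):
        assert bonferroni_threshold(0.05, 15) == pytest.approx(0.00333, abs=5e-6)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestFdrBH:
    def test_all_small_p_rejected(self):
        reject, _ = fdr_bh([0.01] * 21, q=0.05)
        assert reject.all()

    def test_single_p_unchanged(self):
        _, adj = fdr_bh([0.04])
        assert adj[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        # sorted p = (0.001, 0.5); adjusted: min(0.001·2/1, ...) = 0.002, 0.5
        _, adj = fdr_bh([0.001, 0.5])
        assert adj == pytest.approx([0.002, 0.5])

    def test_adjusted_monotone_in_raw_order(self, rng):
        p = rng.uniform(0, 1, 50)
        _, adj = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])


class TestLmm:
    def test_gls_at_zero_variance_equals_ols(self):
        """With σ_b → 0 and ρ = 0 the GLS solution is exactly OLS."""
        table, _ = simulate_cohort(_clean_spec(seed=3))
        res = fit_fc_age_lmm(table.fc, CONN)
        d = table.fc[table.fc["connection"] == CONN]
        ols = smf.ols("z ~ C(visit_age_months)", data=d).fit()
        from infantfc.stats import _gls
        # rebuild the pattern groups exactly as the fitter does
        # evaluate the internal GLS at a frozen theta
        ages = sorted(d["visit_age_months"].unique())
        level = {a: k for k, a in enumerate(ages)}
        by_pattern = {}
        for _, g in d.groupby("subject"):
            g = g.sort_values("visit_age_months")
            if g["visit_age_months"].nunique() < 2:
                continue
            key = tuple(level[a] for a in g["visit_age_months"])
            by_pattern.setdefault(key, []).append(g["z"].to_numpy())
        patterns = []
        for key, ys in by_pattern.items():
            X = np.zeros((len(key), len(ages)))
            X[:, 0] = 1
            for r, k in enumerate(key):
                if k > 0:
                    X[r, k] = 1
            patterns.append((np.array(key, float), X, np.column_stack(ys)))
        beta, _ = _gls(np.array([np.log(1e-12), np.log(0.06), np.arctanh(0.0)]),
                       patterns, len(ages))
        # compare against OLS on the same (>=2-visit) subjects
        kept = d.groupby("subject")["visit_age_months"].nunique()
        d2 = d[d["subject"].isin(kept[kept >= 2].index)]
        ols2 = smf.ols("z ~ C(visit_age_months)", data=d2).fit()
        assert np.allclose(beta, ols2.params.to_numpy(), atol=1e-4)

    def test_cross_check_against_statsmodels_mixedlm(self):
        """With ρ fixed at 0 the model is a random-intercept LMM; REML fixed
        effects and variance components match statsmodels MixedLM."""
        spec = _clean_spec(n_subjects=120, ar1_rho=0.0,
                           missingness_probability=0.2, seed=11)
        table, _ = simulate_cohort(spec)
        mine = fit_fc_age_lmm(table.fc, CONN, fix_rho=0.0)
        d = table.fc[table.fc["connection"] == CONN].copy()
        kept = d.groupby("subject")["visit_age_months"].nunique()
        d = d[d["subject"].isin(kept[kept >= 2].index)]
        md = smf.mixedlm("z ~ C(visit_age_months)", d, groups=d["subject"]).fit(reml=True)
        assert np.allclose(mine.baseline[0], md.params["Intercept"], atol=1e-4)
        theirs = [md.params[f"C(visit_age_months)[T.{a:.1f}]"] for a in (8, 12, 18, 24)]
        ours = [mine.changes[a][0] for a in (8, 12, 18, 24)]
        assert np.allclose(ours, theirs, atol=1e-4)
        assert mine.sigma_b ** 2 == pytest.approx(float(md.cov_re.iloc[0, 0]), abs=2e-3)
        assert mine.sigma_e ** 2 == pytest.approx(md.scale, abs=2e-3)

    def test_recovers_generating_parameters(self):
        spec = CohortSpec(n_subjects=300, missingness_probability=0.0,
                          chromophores=("HbO2",),
                          growth_model=GrowthModel(fc_slopes={}), seed=21)
        table, _ = simulate_cohort(spec)
        res = fit_fc_age_lmm(table.fc, CONN)
        assert res.baseline[0] == pytest.approx(0.28, abs=3 * res.baseline[1])
        truth = {8.0: -0.09, 12.0: -0.20, 18.0: -0.25, 24.0: -0.33}
        for age, (b, se, _) in res.changes.items():
            assert b == pytest.approx(truth[age], abs=3 * se)
        assert res.rho == pytest.approx(0.3, abs=0.15)
        assert res.sigma_e == pytest.approx(0.25, abs=0.04)

    def test_single_visit_subjects_excluded(self):
        d = pd.DataFrame({
            "subject": ["a", "a", "b", "c", "c"],
            "visit_age_months": [5.0, 8.0, 5.0, 5.0, 8.0],
            "connection": CONN, "chromophore": "HbO2",
            "z": [0.1, 0.2, 0.5, 0.15, 0.25],
        })
        res = fit_fc_age_lmm(d, CONN, visit_ages=(5.0, 8.0))
        assert res.n_subjects == 2
        assert res.n_obs == 4

    def test_requires_two_age_levels(self):
        d = pd.DataFrame({"subject": ["a", "b"], "visit_age_months": [5.0, 5.0],
                          "connection": CONN, "chromophore": "HbO2", "z": [0.1, 0.2]})
        with pytest.raises(ValueError):
            fit_fc_age_lmm(d, CONN)


class TestGrowthRegression:
    def test_null_slope_rejection_near_alpha(self):
        rejections = 0
        R = 100
        for r in range(R):
            table, _ = simulate_cohort(_clean_spec(n_subjects=80, seed=500 + r,
                                                   missingness_probability=0.0))
            res = growth_fc_regression(table.fc, table.growth, CONN, ("birth", "24mo"))
            rejections += res.p_value < 0.05
        assert rejections / R == pytest.approx(0.05, abs=0.06)

    def test_covariate_adjustment_runs(self):
        table, _ = simulate_cohort(CohortSpec(n_subjects=100, seed=2,
                                              missingness_probability=0.0))
        for cov in ("WLZ_birth", "HCZ_7_14d"):
            res = growth_fc_regression(table.fc, table.growth, CONN,
                                       ("birth", "24mo"), covariate=cov)
            assert res.covariates == (cov,)
            assert 0 <= res.r_squared <= 1

    def test_collinear_covariate_rejected(self):
        table, _ = simulate_cohort(_clean_spec(missingness_probability=0.0))
        growth = table.growth.copy()
        # make birth WLZ identical to the ΔWLZ predictor: birth = 0, 24mo = x
        piv = growth.pivot_table(index="subject", columns="visit_label", values="wlz")
        dw = piv["24mo"] - piv["birth"]
        growth.loc[growth["visit_label"] == "birth", "wlz"] = dw.loc[
            growth.loc[growth["visit_label"] == "birth", "subject"]].to_numpy()
        growth.loc[growth["visit_label"] == "24mo", "wlz"] = 2 * dw.loc[
            growth.loc[growth["visit_label"] == "24mo", "subject"]].to_numpy()
        with pytest.raises(ValueError, match="rank|collinear"):
            growth_fc_regression(table.fc, growth, CONN, ("birth", "24mo"),
                                 covariate="WLZ_birth")

    def test_too_few_cases_refused(self):
        table, _ = simulate_cohort(_clean_spec(n_subjects=5, missingness_probability=0.0))
        with pytest.raises(ValueError, match="complete cases"):
            growth_fc_regression(table.fc, table.growth, CONN, ("birth", "24mo"))


class TestOutcomeRegression:
    def test_prescribed_slope_recovered(self):
        spec = CohortSpec(n_subjects=200, missingness_probability=0.0, seed=17)
        table, _ = simulate_cohort(spec)
        res = fc_outcome_regression(table.fc, table.outcomes, CONN, 5.0, "younger")
        se = abs(res.slope) / np.sqrt(res.f_stat)
        assert res.slope == pytest.approx(2.0, abs=3 * se)
        assert res.slope_sign == 1

    def test_df_reported_like_simple_regression(self):
        table, _ = simulate_cohort(CohortSpec(n_subjects=120, seed=4))
        res = fc_outcome_regression(table.fc, table.outcomes, CONN, 5.0, "younger")
        assert res.df[0] == 1
        assert res.df[1] == res.n - 2
        assert "F(1," in res.format()

    def test_missing_group_rejected(self):
        table, _ = simulate_cohort(CohortSpec(n_subjects=50, seed=4))
        with pytest.raises(ValueError, match="no outcome scores"):
            fc_outcome_regression(table.fc, table.outcomes, CONN, 5.0, "toddler")
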