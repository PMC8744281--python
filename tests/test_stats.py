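"""GLM battery, FDR, partial correlations, and demographics statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from neuroctrl.stats import (
    CohortError,
    ControllabilityAgeModel,
    chi2_2x2,
    clinical_correlations,
    demographics_table,
    fdr_correct,
    fit_interaction_glm,
    partial_correlation,
    run_primary_analysis,
    subgroup_analysis,
    two_sample_t,
    validate_cohort,
)
from tests.conftest import make_cohort


def _design_matrix(cohort):
    dx = (cohort["diagnosis"] == "SCZ").to_numpy(float)
    age = cohort["age"].to_numpy(float)
    sex = (cohort["sex"] == "M").to_numpy(float)
    edu = cohort["education"].to_numpy(float)
    return np.column_stack([np.ones(len(cohort)), dx, age, dx * age, sex, edu])


class TestInteractionGlm:
    def test_no_interaction_by_construction(self):
        cohort = make_cohort(100, 100, seed=1)
        rng = np.random.default_rng(1)
        y = 2 + 0.5 * cohort["age"].to_numpy() + rng.normal(0, 0.01, 200)
        res = fit_interaction_glm(y, cohort)
        assert res.p_interaction > 0.05
        assert res.coefficients["age"] == pytest.approx(0.5, abs=0.01)

    def test_matches_normal_equations_oracle(self):
        cohort = make_cohort(165, 165, seed=2)
        rng = np.random.default_rng(2)
        dx = (cohort["diagnosis"] == "SCZ").to_numpy(float)
        age = cohort["age"].to_numpy(float)
        sd_y = 1.0
        y = 10 + 0.2 * dx - 0.02 * age + 0.05 * sd_y * dx * age + rng.normal(0, sd_y, 330)
        res = fit_interaction_glm(y, cohort)
        # brute-force OLS via the normal equations
        x = _design_matrix(cohort)
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        sigma2 = resid @ resid / (330 - 6)
        cov = sigma2 * np.linalg.inv(x.T @ x)
        t_int = beta[3] / np.sqrt(cov[3, 3])
        assert res.F_interaction == pytest.approx(t_int**2, abs=1e-8)
        assert res.coefficients["diagnosis_x_age"] == pytest.approx(beta[3], abs=1e-10)
        assert res.n == 330

    def test_twelve_row_worked_dataset(self):
        # small fixture solved by hand linear algebra: (X'X)^{-1} X'y
        cohort = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(12)],
                "diagnosis": ["SCZ"] * 6 + ["HC"] * 6,
                "age": [20.0, 25, 30, 35, 40, 45, 22, 27, 32, 37, 42, 47],
                "sex": ["M", "F"] * 6,
                "education": [10.0, 12, 9, 14, 11, 13, 12, 15, 10, 16, 12, 14],
            }
        )
        y = np.array([1.2, 1.3, 1.1, 1.4, 1.2, 1.5, 1.0, 1.2, 1.3, 1.1, 1.4, 1.3])
        x = _design_matrix(cohort)
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        res = fit_interaction_glm(y, cohort)
        for name, value in zip(
            ("intercept", "diagnosis", "age", "diagnosis_x_age", "sex", "education"),
            beta,
        ):
            assert res.coefficients[name] == pytest.approx(value, abs=1e-10)

    def test_partial_f_equals_squared_t(self):
        import statsmodels.api as sm

        cohort = make_cohort(30, 30, seed=3)
        rng = np.random.default_rng(3)
        y = rng.normal(size=60)
        res = fit_interaction_glm(y, cohort)
        fit = sm.OLS(y, _design_matrix(cohort)).fit()
        assert res.F_interaction == pytest.approx(fit.tvalues[3] ** 2, abs=1e-8)
        # and the p is the F(1, n-6) upper tail of that statistic
        assert res.p_interaction == pytest.approx(
            float(fit.f_test("x3 = 0").pvalue), abs=1e-10
        )

    def test_single_sex_cohort_names_collinear_column(self):
        cohort = make_cohort(15, 15, seed=4)
        cohort["sex"] = "F"
        with pytest.raises(CohortError, match="sex"):
            fit_interaction_glm(np.ones(30) + np.arange(30) * 0.1, cohort)

    def test_small_n_rejected(self):
        cohort = make_cohort(4, 4, seed=5)
        with pytest.raises(CohortError, match="at least 10"):
            fit_interaction_glm(np.arange(8.0), cohort)


class TestFdr:
    def test_benjamini_hochberg_by_hand(self):
        fam = fdr_correct([0.01, 0.02, 0.03, 0.04], q=0.05)
        # p_(4) = 0.04 <= 4 * 0.05 / 4, so the whole family is significant
        assert fam.significant.all()
        np.testing.assert_allclose(fam.adjusted_p, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p, expected", [(0.049, True), (0.051, False)])
    def test_single_test_reduces_to_raw_threshold(self, p, expected):
        assert fdr_correct([p]).significant[0] == expected

    def test_all_null_family_empty(self):
        fam = fdr_correct([0.9] * 8)
        assert not fam.significant.any()
        assert fam.significant_targets == ()

    def test_adjusted_monotone_and_above_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-6, 1, 40)
        fam = fdr_correct(p)
        assert (fam.adjusted_p >= fam.raw_p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(fam.adjusted_p[order]) >= -1e-15).all()
        # significant set is a down-set of ranks
        sig_ranks = np.where(fam.significant[order])[0]
        if sig_ranks.size:
            assert sig_ranks.max() == sig_ranks.size - 1

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [np.nan]])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(CohortError):
            fdr_correct(bad)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 50))
        r, p, n = partial_correlation(x, y)
        pr = scipy.stats.pearsonr(x, y)
        assert r == pytest.approx(pr.statistic, abs=1e-12)
        assert p == pytest.approx(pr.pvalue, abs=1e-12)
        assert n == 50

    def test_identity_gives_unit_correlation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        cov = rng.normal(size=30)
        r, p, _ = partial_correlation(x, x, cov)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_precision_matrix_oracle(self):
        # partial r from the inverse of the correlation matrix of (x, y, z1, z2)
        rng = np.random.default_rng(9)
        z = rng.normal(size=(80, 2))
        x = z @ [0.5, -0.3] + rng.normal(size=80)
        y = z @ [-0.2, 0.4] + 0.5 * x + rng.normal(size=80)
        r, _, _ = partial_correlation(x, y, z)
        corr = np.corrcoef(np.column_stack([x, y, z]).T)
        prec = np.linalg.inv(corr)
        oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=["x", "y", "c1", "c2"])
        r, p, _ = partial_correlation(df["x"], df["y"], df[["c1", "c2"]])
        out = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        p_col = "p_val" if "p_val" in out.columns else "p-val"
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(out[p_col].iloc[0]), abs=1e-10)

    def test_zero_residual_variance_reported_missing(self):
        cov = np.arange(30.0)
        x = 2 * cov + 1  # fully explained by the covariate
        r, p, _ = partial_correlation(x, np.random.default_rng(11).normal(size=30), cov)
        assert np.isnan(r) and np.isnan(p)

    def test_insufficient_n_rejected(self):
        with pytest.raises(CohortError, match="n > k"):
            partial_correlation([1.0, 2, 3], [1.0, 2, 3], [[1.0], [2], [3]])


class TestSummaryStatistics:
    def test_equal_groups_give_zero_t(self):
        t, p, df = two_sample_t(20, 5.0, 1.0, 20, 5.0, 1.0)
        assert t == 0.0
        assert p == pytest.approx(1.0)
        assert df == 38

    def test_pooled_t_matches_hand_formula(self):
        n1, m1, s1, n2, m2, s2 = 14, 3.2, 1.1, 18, 2.5, 0.9
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        expected = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        t, p, _ = two_sample_t(n1, m1, s1, n2, m2, s2)
        assert t == pytest.approx(expected, abs=1e-12)

    def test_proportional_table_independent(self):
        chi2, p = chi2_2x2(10, 10, 20, 20)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi2_matches_expected_count_formula(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            a, b, c, d = rng.integers(1, 60, 4)
            chi2, _ = chi2_2x2(a, b, c, d)
            obs = np.array([[a, b], [c, d]], float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(CohortError, match="margin"):
            chi2_2x2(0, 0, 5, 5)

    def test_demographics_table_structure(self, small_cohort):
        table = demographics_table(small_cohort)
        assert list(table["row"][:3]) == ["Age (years)", "Education (years)", "Sex (M/F)"]
        assert len(table) == 9
        assert (table.loc[3:, "hc"] == "NA").all()  # clinical rows SCZ-only
        assert np.isfinite(table.loc[0, "statistic"])

    def test_demographics_hc_only_has_na_comparisons(self):
        cohort = make_cohort(n_scz=0, n_hc=15, clinical=False)
        table = demographics_table(cohort)
        assert table["statistic"].isna().all()
        assert (table.loc[3:, "scz"] == "NA").all()


class TestCohortValidation:
    def test_age_out_of_range_rejected(self, small_cohort):
        small_cohort.loc[0, "age"] = 70.0
        with pytest.raises(CohortError, match="outside"):
            validate_cohort(small_cohort)

    def test_clinical_values_for_hc_rejected(self, small_cohort):
        small_cohort.loc[small_cohort["diagnosis"] == "HC", "gaf"] = 50.0
        with pytest.raises(CohortError, match="gaf"):
            validate_cohort(small_cohort)

    def test_unknown_diagnosis_rejected(self, small_cohort):
        small_cohort.loc[0, "diagnosis"] = "BIP"
        with pytest.raises(CohortError, match="BIP"):
            validate_cohort(small_cohort)


class TestPrimaryAnalysis:
    def test_output_shape_on_toy_study(self, toy_study):
        cohort, ctrl = toy_study
        res = run_primary_analysis(cohort, ctrl)
        assert len(res.systems) == 8
        assert len(res.nodes) == 20
        frame = res.interactions_frame()
        assert len(frame) == 28
        assert set(frame["family"]) == {"systems", "nodes"}

    def test_injected_dmn_effect_detected_with_correct_signs(self, toy_study):
        cohort, ctrl = toy_study
        res = run_primary_analysis(cohort, ctrl)
        assert "ac_system_DMN" in res.fdr_systems.significant_targets
        traj = {(t.target, t.group): t for t in res.trajectories}
        assert traj[("ac_system_DMN", "HC")].partial_r < 0
        assert traj[("ac_system_DMN", "SCZ")].p > 0.05

    def test_trajectories_only_for_flagged_targets(self, toy_study):
        cohort, ctrl = toy_study
        res = run_primary_analysis(cohort, ctrl)
        flagged = set(res.followup_targets)
        assert {t.target for t in res.trajectories} == flagged
        assert all(
            sum(1 for t in res.trajectories if t.target == f) == 2 for f in flagged
        )

    def test_missing_controllability_subject_rejected(self, toy_study):
        cohort, ctrl = toy_study
        with pytest.raises(CohortError, match="without controllability"):
            run_primary_analysis(cohort, ctrl.iloc[:-1])


class TestSubgroups:
    def test_boundary_ages_split_at_35(self):
        # ages 16 and 35 fall in the younger subgroup, 36 and 60 in the older;
        # each diagnosis sees every boundary age so no subgroup design collapses
        reps = 3
        rng = np.random.default_rng(20)
        cohort = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8 * reps)],
                "diagnosis": ["SCZ", "HC"] * (4 * reps),
                "age": [16.0, 35.0, 36.0, 60.0, 35.0, 16.0, 60.0, 36.0] * reps,
                "sex": list(rng.choice(["M", "F"], 8 * reps)),
                "education": list(rng.uniform(8, 18, 8 * reps)),
            }
        )
        ctrl = pd.DataFrame(
            {
                "subject_id": cohort["subject_id"],
                "ac_system_DMN": rng.normal(1.5, 0.1, 8 * reps),
            }
        )
        out = subgroup_analysis(cohort, ctrl, ["ac_system_DMN"])
        by_model = out[out["model"] == "diagnosis_x_age"].set_index("subgroup")
        assert by_model.loc["younger", "n"] == 4 * reps
        assert by_model.loc["older", "n"] == 4 * reps

    def test_effect_confined_to_older_subgroup_detected_there(self):
        cohort = make_cohort(120, 120, seed=13)
        rng = np.random.default_rng(13)
        age = cohort["age"].to_numpy()
        dx = (cohort["diagnosis"] == "SCZ").to_numpy(float)
        y = rng.normal(0, 0.3, 240)
        older = age > 35
        y[older] += 0.08 * dx[older] * (age[older] - 35)  # interaction only in older
        ctrl = pd.DataFrame({"subject_id": cohort["subject_id"], "ac_system_DMN": 1 + y})
        out = subgroup_analysis(cohort, ctrl, ["ac_system_DMN"]).set_index(
            ["model", "subgroup"]
        )
        assert out.loc[("diagnosis_x_age", "older"), "p_interaction"] < 0.01
        assert out.loc[("diagnosis_x_age", "younger"), "p_interaction"] > 0.05

    def test_empty_cell_rejected(self):
        cohort = make_cohort(15, 15, seed=14)
        cohort.loc[cohort["diagnosis"] == "SCZ", "age"] = 25.0  # no older SCZ
        cohort.loc[cohort["diagnosis"] == "HC", "age"] = np.linspace(20, 55, 15)
        ctrl = pd.DataFrame(
            {"subject_id": cohort["subject_id"], "ac_system_DMN": np.ones(30)}
        )
        with pytest.raises(CohortError, match="empty cell"):
            subgroup_analysis(cohort, ctrl, ["ac_system_DMN"])


class TestClinicalCorrelations:
    def test_null_scores_rarely_significant(self):
        # 200 independent-null replicates: clinical scores unrelated to
        # controllability, so the FDR-significant set should almost always be
        # empty
        n_nonempty = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            cohort = make_cohort(40, 0, seed=1000 + rep)
            ctrl = pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"],
                    "ac_system_DMN": rng.normal(2, 0.2, 40),
                    "ac_system_SUBCORTICAL": rng.normal(2, 0.2, 40),
                }
            )
            frame, fam = clinical_correlations(
                cohort, ctrl, ["ac_system_DMN", "ac_system_SUBCORTICAL"]
            )
            n_nonempty += fam.significant.any()
        assert n_nonempty <= 20  # >= 90% of replicates fully null

    def test_injected_dup_association_recovered(self):
        cohort = make_cohort(60, 0, seed=15)
        rng = np.random.default_rng(15)
        ac = rng.normal(2, 0.2, 60)
        cohort["dup"] = 30 + 40 * (ac - 2) + rng.normal(0, 1.0, 60)
        ctrl = pd.DataFrame({"subject_id": cohort["subject_id"], "ac_system_DMN": ac})
        frame, _ = clinical_correlations(cohort, ctrl, ["ac_system_DMN"])
        row = frame.set_index("measure").loc["dup"]
        assert row["sig_fdr"]
        assert row["partial_r"] > 0.5

    def test_insufficient_n_rejected(self):
        cohort = make_cohort(4, 0, seed=16)
        ctrl = pd.DataFrame(
            {"subject_id": cohort["subject_id"], "ac_system_DMN": np.ones(4)}
        )
        with pytest.raises(CohortError):
            clinical_correlations(cohort, ctrl, ["ac_system_DMN"])


class TestModelInterface:
    def test_fit_produces_summary_and_tables(self, toy_study):
        cohort, ctrl = toy_study
        res = ControllabilityAgeModel(ctrl, cohort).fit()
        text = res.summary()
        assert "ac_system_DMN" in text
        assert len(res.interactions) == 28
        assert {"target", "model", "subgroup"} <= set(res.subgroups.columns)
        assert len(res.clinical) == 6 * len(res.primary.followup_targets)

    def test_rank_transform_preserves_interaction_detection(self, toy_study):
        cohort, ctrl = toy_study
        res = ControllabilityAgeModel(ctrl, cohort, rank_transform=True).fit()
        inter = res.interactions.set_index("target")
        assert inter.loc["ac_system_DMN", "p_interaction"] < 0.05

    def test_plot_trajectory_returns_axis(self, toy_study):
        import matplotlib

        matplotlib.use("Agg")
        cohort, ctrl = toy_study
        res = ControllabilityAgeModel(ctrl, cohort).fit()
        ax = res.plot_trajectory("ac_system_DMN")
        assert ax.get_xlabel() == "age (years)"
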