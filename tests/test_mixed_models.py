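import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swipekin import glmm
from swipekin.mixed_models import (
    ModelSpec,
    chi_square_2x2,
    cohort_tests,
    dispersion_ratio,
    final_model_specs,
    fit_mixed,
    pairwise_correlations,
    prepare_covariates,
    t_from_summary,
    variance_components,
)


class TestPrepareCovariates:
    @pytest.fixture
    def kin(self):
        return pd.DataFrame({
            "participant_id": ["A", "A", "B"],
            "dist_cat": [3, 1, 4],
            "MT": [0.5, 0.6, 0.7],
            "PV": [120.0, 100.0, 140.0],
            "TTPV": [0.2, 0.25, 0.3],
            "PV1": [110.0, 90.0, 140.0],
            "PV1_b": [True, False, True],
            "pct_dec": [50.0, 55.0, 45.0],
            "MU": [1, 2, 1],
            "MU_APV": [0, 1, 0],
        })

    def test_centering(self, kin):
        parts = pd.DataFrame({
            "participant_id": ["A", "B"],
            "group": ["TD", "ASD"],
            "age_months": [56.4, 68.4],  # 4.7 and 5.7 years
        })
        frame = prepare_covariates(kin, parts)
        a = frame[frame.participant_id == "A"].iloc[0]
        b = frame[frame.participant_id == "B"].iloc[0]
        assert a["age_c"] == pytest.approx(0.0)
        assert b["age_c"] == pytest.approx(1.0)
        assert a["asd"] == 0 and b["asd"] == 1
        # category 3 ("30-40") is the centre; category 1 maps to -2
        assert list(frame["dist_c"]) == [0, -2, 1]
        np.testing.assert_allclose(frame["log_MT"], np.log(kin["MT"]))

    def test_missing_age_reported_by_subject(self, kin):
        parts = pd.DataFrame({
            "participant_id": ["A"], "group": ["TD"], "age_months": [50.0]})
        with pytest.raises(ValueError, match="B"):
            prepare_covariates(kin, parts)


class TestFinalSpecs:
    def test_structure(self):
        specs = final_model_specs()
        assert "ASD:age" in specs["MT"].fixed
        assert "ASD:Dist" not in specs["MT"].fixed
        assert specs["PV1_b"].fixed == ("Dist", "age", "ASD")
        assert specs["MU"].family == "ztpoisson"
        assert specs["MU_APV"].family == "poisson"
        assert {"ASD:age", "ASD:Dist"} <= set(specs["MU_APV"].fixed)
        for s in specs.values():
            assert s.random == "intercept_slope"

    def test_estimator_rule(self):
        specs = final_model_specs()
        assert specs["MT"].estimator == "REML"
        assert specs["MU_APV"].estimator == "ML"


class TestGaussianEngine:
    def test_matches_statsmodels_mixedlm(self, small_cohort):
        """Dual route: our profiled REML vs statsmodels MixedLM."""
        import statsmodels.formula.api as smf

        _, frame = small_cohort
        fit = fit_mixed(frame, final_model_specs()["MT"])
        df = frame.copy()
        df["asd_age"] = df["asd"] * df["age_c"]
        ref = smf.mixedlm("log_MT ~ dist_c + age_c + asd + asd_age", df,
                          groups=df["participant_id"], re_formula="~dist_c"
                          ).fit(reml=True)
        np.testing.assert_allclose(fit.table["coef"], ref.fe_params, atol=2e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=0.01)
        assert fit.sigma2 == pytest.approx(ref.scale, rel=0.02)
        assert fit.tau00 == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=0.01)

    def test_satterthwaite_df_in_sensible_range(self, small_cohort):
        _, frame = small_cohort
        fit = fit_mixed(frame, final_model_specs()["MT"])
        n_subjects = frame["participant_id"].nunique()
        # between-subject terms: df near the subject count, not the row count
        for term in ("age", "ASD", "ASD:age"):
            assert 2 < fit.table.loc[term, "df"] < 3 * n_subjects
        assert fit.table.loc["Dist", "df"] > n_subjects

    def test_no_random_effects_degenerates_to_ols(self, small_cohort):
        import statsmodels.api as sm

        _, frame = small_cohort
        spec = ModelSpec("MT", "gaussian", "log", ("Dist", "age", "ASD"),
                         random="none")
        fit = fit_mixed(frame, spec)
        X = np.column_stack([np.ones(len(frame)), frame["dist_c"],
                             frame["age_c"], frame["asd"]])
        ref = sm.OLS(np.log(frame["MT"]), X).fit()
        np.testing.assert_allclose(fit.table["coef"], ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.table["se"], ref.bse, atol=1e-10)

    def test_zero_between_subject_variance_flagged_singular(self, rng):
        n_sub, n_per = 30, 40
        rows = []
        for i in range(n_sub):
            d = rng.integers(-2, 4, n_per)
            y = 0.5 + 0.1 * d + rng.normal(0, 0.3, n_per)  # no subject effect
            for j in range(n_per):
                rows.append((f"S{i}", d[j], y[j]))
        df = pd.DataFrame(rows, columns=["participant_id", "dist_c", "log_MT"])
        df["age_c"] = 0.0
        df["asd"] = 0
        df["MT"] = np.exp(df["log_MT"])
        spec = ModelSpec("MT", "gaussian", "log", ("Dist",))
        fit = fit_mixed(df, spec)
        assert fit.singular
        assert fit.tau00 < 0.01


class TestGlmmEngine:
    def test_matches_glmmtmb(self, small_cohort, tmp_path):
        """Dual route: our Laplace GLMM vs R glmmTMB on the same data."""
        _, frame = small_cohort
        csv = tmp_path / "frame.csv"
        frame.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            m <- glmmTMB(MU_APV ~ dist_c + age_c + asd + asd:age_c + asd:dist_c
                         + (1 + dist_c | participant_id), family = poisson, data = d)
            co <- summary(m)$coefficients$cond
            cat(co[, "Estimate"], "\\n")
            cat(co[, "Std. Error"], "\\n")
            cat(as.numeric(logLik(m)), "\\n")
        """)
        out = subprocess.run(["Rscript", "-"], input=rscript, text=True,
                             capture_output=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = [ln for ln in out.stdout.strip().splitlines() if ln.strip()]
        ref_coef = np.array(lines[0].split(), float)
        ref_se = np.array(lines[1].split(), float)
        ref_llf = float(lines[2])

        fit = fit_mixed(frame, final_model_specs()["MU_APV"])
        # glmmTMB orders interactions after main effects, same as our spec
        np.testing.assert_allclose(fit.table["coef"], ref_coef, atol=5e-3)
        np.testing.assert_allclose(fit.table["se"], ref_se, atol=5e-3)
        assert fit.loglik == pytest.approx(ref_llf, abs=0.05)

    def test_ztp_loglik_matches_scipy_brute_force(self, rng):
        fam = glmm.ZeroTruncatedPoissonLog()
        y = rng.integers(1, 9, 50).astype(float)
        eta = rng.normal(0.5, 0.7, 50)
        mu = np.exp(eta)
        ref = np.log(stats.poisson.pmf(y, mu) / (1 - stats.poisson.pmf(0, mu)))
        np.testing.assert_allclose(fam.loglik(y, eta), ref, atol=1e-9)

    @pytest.mark.parametrize("family", ["binomial", "poisson", "ztpoisson"])
    def test_family_derivatives_match_numerics(self, family, rng):
        fam = glmm.get_family(family)
        y = (rng.integers(1, 6, 30) if family == "ztpoisson"
             else rng.integers(0, 2, 30) if family == "binomial"
             else rng.integers(0, 6, 30)).astype(float)
        eta = rng.normal(0, 1, 30)
        h1, h2 = 1e-6, 1e-4
        d1_num = (fam.loglik(y, eta + h1) - fam.loglik(y, eta - h1)) / (2 * h1)
        d2_num = -(fam.d1(y, eta + h2) - fam.d1(y, eta - h2)) / (2 * h2)
        np.testing.assert_allclose(fam.d1(y, eta), d1_num, atol=1e-5)
        np.testing.assert_allclose(fam.d2(y, eta), d2_num, atol=1e-5)

    def test_exponentiated_ci_consistency(self, small_cohort):
        _, frame = small_cohort
        fit = fit_mixed(frame, final_model_specs()["PV1_b"])
        t = fit.table
        np.testing.assert_allclose(t["exp_ci_low"], np.exp(t["ci_low"]), atol=1e-3)
        np.testing.assert_allclose(t["exp_ci_high"], np.exp(t["ci_high"]), atol=1e-3)
        assert ((t["exp_ci_low"] <= t["exp_coef"])
                & (t["exp_coef"] <= t["exp_ci_high"])).all()


class TestVarianceComponents:
    def test_gaussian_icc_closed_form(self, small_cohort):
        _, frame = small_cohort
        fit = fit_mixed(frame, final_model_specs()["MT"])
        vc = variance_components(fit)
        expect = fit.re_var_mean / (fit.re_var_mean + fit.sigma2)
        assert vc["icc"] == pytest.approx(expect)
        assert vc["r2_conditional"] >= vc["r2_marginal"]
        assert 0 < vc["r2_marginal"] < 1

    def test_logistic_residual_is_pi2_over_3(self, small_cohort):
        _, frame = small_cohort
        fit = fit_mixed(frame, final_model_specs()["PV1_b"])
        vc = variance_components(fit)
        assert vc["residual_variance"] == pytest.approx(np.pi ** 2 / 3)


class TestDispersion:
    def test_poisson_data_near_one(self, small_cohort):
        _, frame = small_cohort
        fit = fit_mixed(frame, final_model_specs()["MU_APV"])
        assert 0.8 < dispersion_ratio(fit) < 1.2

    def test_overdispersed_data_above_one(self, rng):
        rows = []
        for i in range(40):
            lam = np.exp(rng.normal(0.5, 0.4))
            d = rng.integers(-2, 4, 40)
            # negative binomial via gamma-mixed Poisson, strongly overdispersed
            y = rng.poisson(lam * rng.gamma(0.5, 2.0, 40))
            for j in range(40):
                rows.append((f"S{i}", int(d[j]), int(y[j])))
        df = pd.DataFrame(rows, columns=["participant_id", "dist_c", "MU_APV"])
        df["age_c"] = 0.0
        df["asd"] = 0
        fit = fit_mixed(df, ModelSpec("MU_APV", "poisson", "identity", ("Dist",)))
        assert dispersion_ratio(fit) > 1.3

    def test_rejects_non_count_family(self, small_cohort):
        _, frame = small_cohort
        fit = fit_mixed(frame, final_model_specs()["MT"])
        with pytest.raises(ValueError):
            dispersion_ratio(fit)


class TestCorrelations:
    def test_self_correlation_and_identity(self):
        n = 50
        rng = np.random.default_rng(5)
        pv = rng.uniform(50, 200, n)
        kin = pd.DataFrame({
            "TTPV": rng.uniform(0.1, 0.4, n), "MT": rng.uniform(0.2, 1.0, n),
            "MU": rng.integers(1, 5, n), "pct_dec": rng.uniform(30, 70, n),
            "MU_APV": rng.integers(0, 3, n), "PV1_b": rng.integers(0, 2, n),
            "PV1": pv, "PV": pv,  # identical columns
        })
        corr = pairwise_correlations(kin)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["PV1", "PV"] == pytest.approx(1.0)
        pd.testing.assert_frame_equal(corr, corr.T)

    def test_constant_column_warns(self):
        kin = pd.DataFrame({"PV": [1.0, 2.0, 3.0], "MT": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="MT"):
            corr = pairwise_correlations(kin)
        assert np.isnan(corr.loc["MT", "PV"])

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            pairwise_correlations(pd.DataFrame({"PV": [1.0, 2.0]}))


class TestCohortTests:
    def test_published_exclusion_table_chi2(self):
        """2x2 excluded/analysed by group: Pearson p = 0.385, Yates p = 0.406."""
        table = np.array([[640, 2593], [351, 1333]])
        plain = chi_square_2x2(table, correction=False)
        yates = chi_square_2x2(table, correction=True)
        assert plain["statistic"] == pytest.approx(0.755, abs=0.005)
        assert plain["p"] == pytest.approx(0.385, abs=0.005)
        assert yates["p"] == pytest.approx(0.406, abs=0.005)

    def test_published_sex_table_chi2(self):
        # male/female by group: 30/13 (TD) vs 17/11 (ASD)
        res = chi_square_2x2(np.array([[30, 13], [17, 11]]), correction=False)
        assert res["statistic"] == pytest.approx(0.621, abs=0.01)
        assert res["p"] == pytest.approx(0.431, abs=0.01)

    def test_published_swipes_per_participant_t(self):
        # group means (sd, n): 73.3 (25.6, 43) vs 54.8 (25.4, 28)
        res = t_from_summary(73.3, 25.6, 43, 54.8, 25.4, 28)
        assert res["df"] == 69
        assert res["statistic"] == pytest.approx(2.99, abs=0.02)
        assert res["p"] == pytest.approx(0.004, abs=0.001)

    def test_published_dist_distribution_chi2(self):
        td = [172, 808, 467, 552, 429, 165]
        asd = [60, 399, 276, 299, 214, 85]
        chi2, p, dof, _ = stats.chi2_contingency(np.array([td, asd]))
        assert dof == 5
        assert chi2 == pytest.approx(11.2, abs=0.15)
        assert p == pytest.approx(0.047, abs=0.005)

    def test_identical_groups_null(self):
        rng = np.random.default_rng(11)
        subj = [f"S{i}" for i in range(20)]
        ages = rng.uniform(36, 72, 10)
        parts = pd.DataFrame({
            "participant_id": subj,
            "group": ["TD"] * 10 + ["ASD"] * 10,
            "age_months": np.r_[ages, ages],  # identical age distributions
            "sex": ["M", "F"] * 10,
        })
        rows = []
        for i, s in enumerate(subj):
            for k in range(5 + (i % 10) % 4):  # same count pattern in both groups
                rows.append((s, parts["group"][i], 1 + (k % 6)))
        frame = pd.DataFrame(rows, columns=["participant_id", "group", "dist_cat"])
        out = cohort_tests(frame, parts)
        assert out["age_t"]["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert out["age_t"]["p"] == pytest.approx(1.0, abs=1e-9)
        assert out["swipes_per_participant_t"]["statistic"] == pytest.approx(0.0)
        assert out["dist_by_group"]["p"] == pytest.approx(1.0)

    def test_cohort_tests_on_simulated_frame(self, small_cohort):
        _, frame = small_cohort
        parts = frame.drop_duplicates("participant_id")[
            ["participant_id", "group", "age_months"]].copy()
        parts["sex"] = ["M", "F"] * (len(parts) // 2) + ["M"] * (len(parts) % 2)
        out = cohort_tests(frame, parts)
        for key in ("age_t", "age_var_f", "swipes_per_participant_t",
                    "dist_by_group", "dist_mannwhitney", "sex_by_group"):
            assert key in out
            assert 0 <= out[key]["p"] <= 1
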