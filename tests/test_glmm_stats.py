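import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import songrhythm.glmm_stats as g
from songrhythm.glmm_stats import (
    BETA_LOGIT,
    POISSON_LOG,
    ModelSpec,
    check_zero_inflation,
    fit_beta_glmm,
    fit_glmm,
    fit_poisson_glmm,
    likelihood_ratio_test,
    null_spec,
    pairwise_contrasts,
)


def simulate_poisson_bins(
    n_groups=50, seed=0, sigma=0.5, beta_bin=None, beta_sex=0.4, obs_per_group=1
):
    """Draw from the bin-count model itself (the recovery oracle)."""
    rng = np.random.default_rng(seed)
    bins = ["on_R12", "off_R12", "on_R11", "off_R11", "on_R21", "off_R21"]
    if beta_bin is None:
        beta_bin = dict(zip(bins, [1.0, 0.0, 2.0, 0.3, 1.2, 0.1]))
    rows = []
    for i in range(n_groups):
        u = rng.normal(0, sigma)
        sex = "F" if i % 2 == 0 else "M"
        for _ in range(obs_per_group):
            for b in bins:
                eta = beta_bin[b] + (beta_sex if sex == "M" else 0.0) + u
                rows.append(
                    {
                        "count": rng.poisson(np.exp(eta)),
                        "bin": b,
                        "sex": sex,
                        "log_width": 0.0,
                        "individual_id": f"g{i:03d}",
                    }
                )
    return pd.DataFrame(rows)


class TestPoissonGlmm:
    def test_intercept_only_boundary_gives_log_mean(self):
        df = pd.DataFrame(
            {
                "count": [1, 2, 3],
                "log_width": [0.0] * 3,
                "individual_id": ["a", "b", "c"],
            }
        )
        spec = ModelSpec(response="count", offset="log_width", family=POISSON_LOG)
        with pytest.warns(UserWarning, match="one observation per level"):
            fit = fit_glmm(df, spec)
        # observed variance (1) < Poisson variance (2): sigma2 hits the floor
        assert fit.sigma2_u < 1e-4
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-3)

    def test_sigma_zero_equals_plain_poisson_regression(self):
        import patsy
        import statsmodels.api as sm

        df = simulate_poisson_bins(n_groups=30, seed=1)
        fit = fit_poisson_glmm(df, fix_sigma=0.0)
        _, X = patsy.dmatrices("count ~ C(bin)*C(sex)", df, return_type="dataframe")
        glm = sm.GLM(
            df["count"].to_numpy(),
            np.asarray(X),
            family=sm.families.Poisson(),
            offset=df["log_width"].to_numpy(),
        ).fit()
        assert np.max(np.abs(fit.beta - glm.params)) < 1e-6
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_parameter_recovery_within_three_se(self):
        sigma = 0.5  # sigma2_u = 0.25
        df = simulate_poisson_bins(n_groups=50, seed=2, sigma=sigma)
        fit = fit_poisson_glmm(df)
        assert fit.converged
        # truth on the treatment-coded scale
        import patsy

        truth_eta = {}
        bins = ["on_R12", "off_R12", "on_R11", "off_R11", "on_R21", "off_R21"]
        beta_bin = dict(zip(bins, [1.0, 0.0, 2.0, 0.3, 1.2, 0.1]))
        grid = pd.DataFrame(
            [(b, s) for b in bins for s in ["F", "M"]], columns=["bin", "sex"]
        )
        (Xg,) = patsy.build_design_matrices(
            [fit._design_info], grid, return_type="dataframe"
        )
        eta_true = np.array(
            [beta_bin[b] + (0.4 if s == "M" else 0.0) for b, s in zip(grid["bin"], grid["sex"])]
        )
        beta_true, *_ = np.linalg.lstsq(np.asarray(Xg), eta_true, rcond=None)
        se = fit.se_beta()
        assert np.all(np.abs(fit.beta - beta_true) < 3 * se)
        # the random-intercept SD is recovered to the right order
        assert 0.05 < fit.sigma2_u < 1.0

    def test_offset_shift_moves_only_the_intercept(self):
        df = simulate_poisson_bins(n_groups=30, seed=3)
        base = fit_poisson_glmm(df)
        shifted = df.copy()
        shifted["log_width"] = shifted["log_width"] + np.log(2.0)
        alt = fit_poisson_glmm(shifted)
        assert alt.beta[0] == pytest.approx(base.beta[0] - np.log(2.0), abs=1e-4)
        assert np.allclose(alt.beta[1:], base.beta[1:], atol=1e-4)
        ct_a = pairwise_contrasts(base, "bin", by="sex")
        ct_b = pairwise_contrasts(alt, "bin", by="sex")
        assert np.allclose(ct_a["estimate"], ct_b["estimate"], atol=1e-4)

    def test_non_integer_counts_rejected(self):
        df = pd.DataFrame(
            {"count": [1.5, 2.0], "log_width": [0.0, 0.0], "individual_id": ["a", "a"]}
        )
        with pytest.raises(ValueError, match="nonnegative integers"):
            fit_glmm(df, ModelSpec(response="count", offset="log_width"))

    def test_agq_refines_laplace_consistently(self):
        df = simulate_poisson_bins(n_groups=20, seed=4, sigma=0.8)
        lap = fit_poisson_glmm(df)
        agq = fit_poisson_glmm(df, n_agq=15)
        # Poisson Laplace is already accurate; AGQ must agree closely
        assert np.max(np.abs(lap.beta - agq.beta)) < 0.02
        assert abs(lap.loglik - agq.loglik) < 0.5


class TestBetaGlmm:
    def test_mean_recovery_no_covariates(self):
        rng = np.random.default_rng(3)
        y = rng.beta(0.7 * 20, 0.3 * 20, 500)
        df = pd.DataFrame(
            {"regularity": y, "contribution_id": [f"c{i}" for i in range(500)]}
        )
        with pytest.warns(UserWarning, match="weakly identified"):
            fit = fit_beta_glmm(
                df,
                ModelSpec(
                    response="regularity",
                    group="contribution_id",
                    family=BETA_LOGIT,
                ),
            )
        assert expit(fit.beta[0]) == pytest.approx(0.7, abs=0.03)

    def test_exact_boundary_response_rejected_with_guidance(self):
        df = pd.DataFrame(
            {"regularity": [0.5, 0.0], "contribution_id": ["a", "b"]}
        )
        with pytest.raises(ValueError, match="boundary compression transform"):
            fit_beta_glmm(
                df,
                ModelSpec(
                    response="regularity", group="contribution_id", family=BETA_LOGIT
                ),
            )

    def test_sex_age_effect_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        rows = []
        truth = {"F": 0.5, "M": 0.9}
        for s in ["F", "M"]:
            for a in ["ADULT", "JUV_3_4", "YOUNG_0_2"]:
                for i in range(25):
                    u = rng.normal(0, 0.3)
                    for j in range(3):
                        eta = truth[s] + (0.3 if a == "ADULT" else 0.0) + u
                        mu, phi = expit(eta), 15
                        rows.append(
                            {
                                "regularity": rng.beta(mu * phi, (1 - mu) * phi),
                                "sex": s,
                                "age_class": a,
                                "individual_id": f"{s}{a}{i}",
                            }
                        )
        df = pd.DataFrame(rows)
        fit = fit_glmm(
            df,
            ModelSpec(
                response="regularity",
                factors=("sex", "age_class"),
                group="individual_id",
                family=BETA_LOGIT,
            ),
        )
        assert fit.converged
        # truth in treatment coding (ADULT/F reference):
        # intercept 0.8, sex[M] 0.4? no: eta(F,ADULT)=0.8, eta(M,ADULT)=1.2,
        # eta(F,other)=0.5 -> age effects -0.3; no interaction
        truth_beta = np.array([0.8, 0.4, -0.3, -0.3, 0.0, 0.0])
        se = fit.se_beta()
        assert np.all(np.abs(fit.beta - truth_beta) < 3 * se)
        assert 5 < fit.phi < 40


class TestLRT:
    def test_identical_models_give_zero_statistic(self):
        df = simulate_poisson_bins(n_groups=10, seed=5)
        fit = fit_poisson_glmm(df)
        res = likelihood_ratio_test(fit, fit)
        assert res.statistic == 0.0 and res.p == 1.0 and res.df == 0

    def test_df_is_the_extra_fixed_parameter_count(self):
        df = simulate_poisson_bins(n_groups=10, seed=6)
        full = fit_poisson_glmm(df)
        null = fit_glmm(df, null_spec(full.spec))
        res = likelihood_ratio_test(full, null)
        assert full.n_fixed == 12 and null.n_fixed == 1  # 6x2 interaction design
        assert res.df == 11
        assert res.statistic >= 0

    def test_differing_row_counts_rejected(self):
        df = simulate_poisson_bins(n_groups=10, seed=7)
        full = fit_poisson_glmm(df)
        null = fit_glmm(df.iloc[:-6], null_spec(full.spec))
        with pytest.raises(ValueError, match="different row counts"):
            likelihood_ratio_test(full, null)


class TestContrasts:
    def test_two_level_factor_tukey_equals_unadjusted(self):
        df = simulate_poisson_bins(n_groups=20, seed=8)
        fit = fit_poisson_glmm(df)
        tukey = pairwise_contrasts(fit, "sex", adjust="tukey")
        plain = pairwise_contrasts(fit, "sex", adjust="none")
        assert len(tukey) == 1
        assert tukey["p_adj"][0] == pytest.approx(plain["p_adj"][0], rel=1e-6)

    def test_six_level_factor_gives_fifteen_rows(self):
        df = simulate_poisson_bins(n_groups=20, seed=9)
        fit = fit_poisson_glmm(df)
        ct = pairwise_contrasts(fit, "bin")
        assert len(ct) == 15

    def test_within_sex_families(self):
        df = simulate_poisson_bins(n_groups=20, seed=10)
        fit = fit_poisson_glmm(df)
        ct = pairwise_contrasts(fit, "bin", by="sex")
        assert len(ct) == 30
        assert set(ct["sex"]) == {"F", "M"}

    def test_unknown_factor_rejected(self):
        df = simulate_poisson_bins(n_groups=10, seed=11)
        fit = fit_poisson_glmm(df)
        with pytest.raises(ValueError, match="not in the model"):
            pairwise_contrasts(fit, "age_class")


class TestZeroInflation:
    def test_no_zeros_gives_ratio_zero(self):
        df = simulate_poisson_bins(n_groups=20, seed=12)
        df["count"] = df["count"] + 1  # force all-positive
        fit = fit_poisson_glmm(df)
        res = check_zero_inflation(fit)
        assert res.observed_zeros == 0 and res.ratio == 0.0 and not res.inflated

    def test_self_consistent_data_near_one(self):
        df = simulate_poisson_bins(n_groups=80, seed=13, sigma=0.3)
        fit = fit_poisson_glmm(df)
        res = check_zero_inflation(fit)
        assert 0.9 <= res.ratio <= 1.1

    def test_structural_zeros_flagged(self):
        rng = np.random.default_rng(14)
        df = simulate_poisson_bins(n_groups=80, seed=14, sigma=0.3)
        mask = rng.random(len(df)) < 0.3
        df.loc[mask, "count"] = 0
        fit = fit_poisson_glmm(df)
        res = check_zero_inflation(fit)
        assert res.inflated and res.ratio > 1.05

    def test_requires_poisson_family(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            {
                "regularity": rng.beta(5, 2, 60),
                "individual_id": [f"i{k % 20}" for k in range(60)],
            }
        )
        fit = fit_glmm(
            df,
            ModelSpec(response="regularity", group="individual_id", family=BETA_LOGIT),
        )
        with pytest.raises(ValueError, match="Poisson"):
            check_zero_inflation(fit)


class TestCrossValidationAgainstR:
    def test_poisson_glmm_matches_glmmTMB_laplace(self, tmp_path):
        """Independent oracle: the same model fitted by glmmTMB in R."""
        df = simulate_poisson_bins(n_groups=20, seed=21, sigma=0.5)
        fit = fit_glmm(
            df,
            ModelSpec(
                response="count",
                factors=("bin",),
                interaction=False,
                offset="log_width",
                group="individual_id",
                family=POISSON_LOG,
            ),
        )
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            m <- glmmTMB(count ~ bin + offset(log_width) + (1 | individual_id),
                         family = poisson, data = d)
            cat(sprintf("%.10f\\n", logLik(m)))
            cat(sprintf("%.10f\\n", fixef(m)$cond))
            cat(sprintf("%.10f\\n", VarCorr(m)$cond$individual_id[1]))
            """
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.split()]
        r_ll, r_beta, r_sigma2 = vals[0], np.array(vals[1:7]), vals[7]
        assert fit.loglik == pytest.approx(r_ll, abs=1e-3)
        assert np.max(np.abs(fit.beta - r_beta)) < 1e-3
        assert fit.sigma2_u == pytest.approx(r_sigma2, abs=1e-3)
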