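"""Longitudinal mixed models, logistic GLMM and likelihood-ratio tests."""

import numpy as np
import pandas as pd
import pytest

from disconnectome import (
    SimulationConfig,
    binarize_ilae,
    fit_binary_glmm,
    fit_change_lmm,
    gen_cohort,
    likelihood_ratio_test,
)


def _model_frame(rng, n=60, beta_x=0.0, subject_sd=0.3, noise_sd=0.3):
    """Long-format change table generated directly from the LMM."""
    rows = []
    for i in range(n):
        age_s = rng.uniform(20, 60)
        age_o = rng.uniform(5, age_s - 5)
        resvol = rng.uniform(0.01, 0.1)
        pre = rng.normal(-0.5, 1)
        x = rng.uniform(0, 1)
        u = rng.normal(0, subject_sd)
        for tp, is12 in (("3m", 0), ("12m", 1)):
            y = 0.2 + 0.25 * is12 - 0.01 * age_s - 1.0 * resvol - 0.2 * pre + beta_x * x + u
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "timepoint": tp,
                    "change_z": y + rng.normal(0, noise_sd),
                    "age_surgery": age_s,
                    "age_onset": age_o,
                    "resection_volume": resvol,
                    "pre_z": pre,
                    "tract": x,
                }
            )
    return pd.DataFrame(rows)


class TestChangeLMM:
    def test_noise_free_data_recovers_coefficients_exactly(self, rng):
        df = _model_frame(rng, n=40, beta_x=-0.5, subject_sd=0.0, noise_sd=0.0)
        fit = fit_change_lmm(df, tract_term="tract")
        assert fit.converged
        assert fit.params["tract"] == pytest.approx(-0.5, abs=1e-6)
        assert fit.params["age_surgery"] == pytest.approx(-0.01, abs=1e-6)
        assert fit.params["resection_volume"] == pytest.approx(-1.0, abs=1e-6)

    def test_recovers_effect_with_noise(self, rng):
        df = _model_frame(rng, n=150, beta_x=-0.5)
        fit = fit_change_lmm(df, tract_term="tract")
        assert fit.converged
        assert fit.params["tract"] == pytest.approx(-0.5, abs=0.35)
        assert fit.re_var > 0

    def test_timepoint_reference_is_3m(self, rng):
        df = _model_frame(rng, n=120, beta_x=0.0)
        fit = fit_change_lmm(df)
        tp_term = [k for k in fit.params.index if "timepoint" in k]
        assert len(tp_term) == 1 and "12m" in tp_term[0]
        # scores recover by 12 months relative to 3 months: positive shift
        assert fit.params[tp_term[0]] > 0

    def test_duplicate_tract_term_rejected(self, rng):
        df = _model_frame(rng)
        df["tract"] = df["resection_volume"]
        with pytest.raises(ValueError, match="collinear"):
            fit_change_lmm(df, tract_term="tract")

    def test_missing_rows_dropped_subjects_retained(self, rng):
        df = _model_frame(rng, n=30)
        df.loc[df["timepoint"] == "12m", "change_z"] = np.where(
            rng.uniform(size=30) < 0.4, np.nan, df.loc[df["timepoint"] == "12m", "change_z"]
        )
        fit = fit_change_lmm(df)
        assert fit.n_obs == df["change_z"].notna().sum()
        assert fit.n_subjects == 30  # one-timepoint subjects stay in

    def test_no_within_subject_correlation_gives_near_zero_variance(self, rng):
        df = _model_frame(rng, n=120, subject_sd=0.0, noise_sd=0.5)
        fit = fit_change_lmm(df)
        assert fit.re_var < 0.05


class TestLRT:
    def test_same_model_twice_is_null(self, rng):
        df = _model_frame(rng)
        fit = fit_change_lmm(df)
        res = likelihood_ratio_test(fit, fit)
        assert res.chi_sq == 0.0
        assert res.p == 1.0

    def test_one_added_term_gives_df_one(self, rng):
        df = _model_frame(rng)
        null = fit_change_lmm(df)
        full = fit_change_lmm(df, tract_term="tract")
        res = likelihood_ratio_test(null, full)
        assert res.df == 1
        assert res.chi_sq >= 0.0
        assert 0 <= res.p <= 1

    def test_mismatched_rows_rejected(self, rng):
        df = _model_frame(rng)
        null = fit_change_lmm(df)
        full = fit_change_lmm(df.iloc[: len(df) - 4], tract_term="tract")
        with pytest.raises(ValueError, match="rows"):
            likelihood_ratio_test(null, full)

    def test_invariant_to_covariate_rescaling(self, rng):
        df = _model_frame(rng, n=100, beta_x=-0.4)
        null1, full1 = fit_change_lmm(df), fit_change_lmm(df, tract_term="tract")
        df2 = df.copy()
        df2["tract"] = df2["tract"] * 100.0
        df2["age_surgery"] = df2["age_surgery"] / 10.0
        null2, full2 = fit_change_lmm(df2), fit_change_lmm(df2, tract_term="tract")
        r1 = likelihood_ratio_test(null1, full1)
        r2 = likelihood_ratio_test(null2, full2)
        assert r1.chi_sq == pytest.approx(r2.chi_sq, abs=0.02)


def _glmm_frame(rng, n=150, beta=2.0, sigma=0.8):
    rows = []
    for i in range(n):
        x = int(rng.integers(0, 2))
        u = rng.normal(0, sigma)
        resvol = rng.uniform(0.01, 0.1)
        for _ in range(2):
            eta = -0.5 + beta * x + u
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "y": int(rng.uniform() < 1.0 / (1.0 + np.exp(-eta))),
                    "x": x,
                    "resection_volume": resvol,
                }
            )
    return pd.DataFrame(rows)


class TestBinaryGLMM:
    def test_recovers_log_odds(self, rng):
        df = _glmm_frame(rng, n=150, beta=2.0)
        fit = fit_binary_glmm(df, outcome="y", predictor="x")
        assert fit.converged
        # truth inside the Wald 95% CI and close on the log-odds scale
        assert abs(fit.params["x"] - 2.0) < 2.0 * fit.bse["x"] + 0.2
        assert abs(fit.params["x"] - 2.0) < 0.8

    def test_type_one_error_calibrated(self, rng):
        """Under independence the LRT rejects at ~alpha (simulation)."""
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            df = _glmm_frame(rng, n=60, beta=0.0, sigma=0.5)
            # confound-only vs confound-plus-predictor, outcome independent of x
            full = fit_binary_glmm(df, outcome="y", predictor="x", covariates=("resection_volume",))
            null = fit_binary_glmm(df, outcome="y", predictor="resection_volume", covariates=())
            lrt = likelihood_ratio_test(null, full)
            rejections += lrt.p < 0.05
        rate = rejections / n_sim
        assert 0.02 < rate < 0.09

    def test_degenerate_outcome_rejected(self, rng):
        df = _glmm_frame(rng)
        df["y"] = 1
        with pytest.raises(ValueError, match="degenerate"):
            fit_binary_glmm(df, outcome="y", predictor="x")

    def test_separation_triggers_penalized_fallback(self, rng):
        df = _glmm_frame(rng, n=40, beta=0.0)
        df["y"] = df["x"]  # perfectly separated
        fit = fit_binary_glmm(df, outcome="y", predictor="x", covariates=())
        assert fit.penalized
        assert np.isfinite(fit.params["x"])

    def test_single_observation_per_subject_drops_random_intercept(self, rng):
        df = _glmm_frame(rng).groupby("subject_id", as_index=False).first()
        fit = fit_binary_glmm(df, outcome="y", predictor="x", covariates=())
        assert fit.re_var == 0.0


class TestIlae:
    @pytest.mark.parametrize("ilae, expected", [(1, 1), (2, 0), (3, 0), (5, 0)])
    def test_binarization(self, ilae, expected):
        assert binarize_ilae(ilae) == expected

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            binarize_ilae(0)


class TestPowerMonotonicity:
    def test_lrt_statistic_grows_with_effect_size(self):
        """Mean LRT chi-square increases monotonically in |beta_transect|."""
        means = []
        for beta in (0.0, -0.4, -0.8):
            chis = []
            for seed in range(6):
                cfg = SimulationConfig(n_subjects=50, seed=1000 + seed, beta_transect=beta)
                coh = gen_cohort(cfg, include_maps=False)
                lt = coh.long_table("encoding")
                null = fit_change_lmm(lt)
                full = fit_change_lmm(lt, tract_term="transection")
                chis.append(likelihood_ratio_test(null, full).chi_sq)
            means.append(np.mean(chis))
        assert means[0] < means[1] < means[2]
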