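"""Random-intercept model fitting, ICC, and the end-to-end analysis."""

import warnings

import numpy as np
import pandas as pd
import pytest

import taumem as tm
from taumem.models import build_design


def _clustered_frame(seed, N=60, T=4, tau00=0.0, sigma2=0.49):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "pid": np.repeat(np.arange(N), T),
        "biomarker_change": rng.normal(0, .03, N * T),
        "sex": np.repeat(rng.integers(0, 2, N).astype(float), T),
        "age_c": np.repeat(rng.normal(0, 6, N), T),
        "edu_c": np.repeat(rng.normal(0, 2.5, N), T),
        "apoe4": np.repeat(rng.integers(0, 2, N).astype(float), T),
    })
    b = np.repeat(rng.normal(0, np.sqrt(tau00), N), T)
    df["memory_change"] = (0.2 - 20 * df.biomarker_change - 0.1 * df.sex
                           + b + rng.normal(0, np.sqrt(sigma2), N * T))
    return df


class TestICC:
    def test_printed_variance_components(self):
        assert tm.icc(0.12, 0.56) == pytest.approx(0.17647, abs=1e-4)
        assert round(tm.icc(0.12, 0.56), 2) == 0.18

    def test_degenerate_and_symmetric_cases(self):
        assert tm.icc(0.0, 0.5) == 0.0
        for x in (0.01, 1.0, 7.3):
            assert tm.icc(x, x) == pytest.approx(0.5)

    def test_invalid_components_rejected(self):
        with pytest.raises(ValueError):
            tm.icc(0.1, 0.0)
        with pytest.raises(ValueError):
            tm.icc(-0.1, 0.5)


class TestDesign:
    def test_interaction_columns_are_products(self, cohort_direct):
        frame = tm.direct_model_frame(cohort_direct)
        X = build_design(frame, tm.FULL_TERMS)
        np.testing.assert_allclose(
            X["biomarker_change:sex:group"],
            frame.biomarker_change * frame.sex * frame.group)

    def test_rank_deficiency_names_aliased_terms(self):
        df = _clustered_frame(0)
        df["edu_c"] = df["age_c"]  # perfectly aliased
        with pytest.raises(ValueError, match="aliased"):
            build_design(df, tm.STRATIFIED_TERMS)


class TestFitLMM:
    def test_boundary_tau00_matches_ols(self):
        """Data without between-participant variance: REML hits the zero
        boundary and the fixed effects coincide with plain OLS."""
        df = _clustered_frame(seed=10, tau00=0.0)
        with pytest.warns(UserWarning, match="boundary"):
            fit = tm.fit_lmm(df, tm.STRATIFIED_TERMS)
        X = build_design(df, tm.STRATIFIED_TERMS).to_numpy()
        ols = np.linalg.lstsq(X, df.memory_change.to_numpy(), rcond=None)[0]
        assert fit.tau00 < 1e-8
        np.testing.assert_allclose(fit.params.estimate.to_numpy(), ols,
                                   atol=1e-6)

    def test_fixed_variance_gls_matches_dense_oracle(self):
        """Tiny balanced fixture vs. brute-force GLS with the full dense
        covariance matrix."""
        rng = np.random.default_rng(2)
        N, T, tau00, sigma2 = 4, 2, 0.3, 0.7
        df = pd.DataFrame({
            "pid": np.repeat(np.arange(N), T),
            "biomarker_change": rng.normal(0, 1, N * T),
            "sex": np.repeat([0.0, 1.0, 0.0, 1.0], T),
            "age_c": np.repeat(rng.normal(0, 5, N), T),
            "edu_c": rng.normal(0, 2, N * T),
            "apoe4": np.repeat([0.0, 0.0, 1.0, 1.0], T),
        })
        df["memory_change"] = rng.normal(0, 1, N * T)
        terms = ("intercept", "biomarker_change", "sex")
        fit = tm.fit_lmm(df, terms, fix_variance=(tau00, sigma2))

        X = build_design(df, terms).to_numpy()
        y = df.memory_change.to_numpy()
        g = df.pid.to_numpy()
        V = sigma2 * np.eye(N * T) + tau00 * (g[:, None] == g[None, :])
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ Vi @ X)))
        np.testing.assert_allclose(fit.params.estimate, beta, atol=1e-8)
        np.testing.assert_allclose(fit.params.se, se, atol=1e-8)

    def test_recovers_generating_variance_components(self):
        df = _clustered_frame(seed=1, N=400, T=4, tau00=0.12, sigma2=0.56)
        fit = tm.fit_lmm(df, tm.STRATIFIED_TERMS)
        assert fit.converged
        assert fit.tau00 == pytest.approx(0.12, abs=0.05)
        assert fit.sigma2 == pytest.approx(0.56, abs=0.06)
        assert fit.icc == pytest.approx(tm.icc(fit.tau00, fit.sigma2))

    def test_reml_ml_fixed_effects_nearly_identical(self):
        df = _clustered_frame(seed=3, N=300, T=4, tau00=0.12)
        reml = tm.fit_lmm(df, tm.STRATIFIED_TERMS, reml=True)
        ml = tm.fit_lmm(df, tm.STRATIFIED_TERMS, reml=False)
        np.testing.assert_allclose(reml.params.estimate, ml.params.estimate,
                                   atol=0.02)
        assert ml.sigma2 != reml.sigma2  # variance components do differ

    def test_icc_invariant_to_outcome_rescaling(self):
        df = _clustered_frame(seed=4, N=200, T=4, tau00=0.12)
        fit1 = tm.fit_lmm(df, tm.STRATIFIED_TERMS)
        df2 = df.copy()
        df2["memory_change"] *= 3.0
        fit2 = tm.fit_lmm(df2, tm.STRATIFIED_TERMS)
        assert fit1.icc == pytest.approx(fit2.icc, abs=1e-4)

    def test_wald_ci_brackets_estimate(self, cohort_direct):
        fit = tm.fit_lmm(tm.direct_model_frame(cohort_direct))
        assert (fit.params.ci_low < fit.params.estimate).all()
        assert (fit.params.estimate < fit.params.ci_high).all()
        assert fit.sigma2 > 0 and fit.tau00 >= 0
        assert 0 <= fit.icc < 1

    def test_non_finite_outcome_rejected(self):
        df = _clustered_frame(0)
        df.loc[0, "memory_change"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            tm.fit_lmm(df, tm.STRATIFIED_TERMS)


class TestFullAnalysis:
    def test_four_fits_and_metadata(self, analysis_raw):
        assert set(analysis_raw.fits) == {"full", "preclinical", "mci",
                                          "sensitivity"}
        meta = analysis_raw.metadata
        assert meta["n_by_model"]["full"] == \
            meta["n_by_model"]["preclinical"] + meta["n_by_model"]["mci"]
        assert meta["n_by_model"]["sensitivity"] <= meta["n_by_model"]["mci"]
        full = analysis_raw.fits["full"]
        assert list(full.params.index) == list(tm.FULL_TERMS)
        assert list(analysis_raw.fits["mci"].params.index) \
            == list(tm.STRATIFIED_TERMS)

    def test_sensitivity_is_noop_when_all_mci_positive(self, cohort_raw,
                                                       norms):
        coh = cohort_raw.copy()
        coh["biomarker_positive"] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = tm.run_full_analysis(coh, norms=norms)
        pd.testing.assert_frame_equal(res.fits["sensitivity"].params,
                                      res.fits["mci"].params)

    def test_single_sex_stratum_rejected(self, cohort_direct):
        from taumem.models import _stratum_fit
        frame = tm.direct_model_frame(cohort_direct)
        males_only = frame[frame.sex_label == "male"]
        with pytest.raises(ValueError, match="single sex"):
            _stratum_fit(males_only, "mci", reml=True)

    def test_no_analysis_groups_rejected(self, cohort_raw, norms):
        coh = cohort_raw.copy()
        coh["biomarker_positive"] = False
        coh["biomarker_ratio"] = 0.001
        coh = coh[coh.group == "preclinical"]  # all become CN-negative
        with pytest.raises(ValueError, match="no analysis groups"):
            tm.run_full_analysis(coh, norms=norms)

    def test_norms_or_reference_required(self, cohort_raw):
        with pytest.raises(ValueError, match="norms"):
            tm.run_full_analysis(cohort_raw)

    def test_direct_frame_requires_truth_columns(self, cohort_raw):
        with pytest.raises(ValueError, match="direct"):
            tm.direct_model_frame(cohort_raw)

    def test_sex_coding_flip_negates_sex_effect(self, cohort_direct):
        f1 = tm.fit_lmm(tm.direct_model_frame(cohort_direct, female_code=1))
        f0 = tm.fit_lmm(tm.direct_model_frame(cohort_direct, female_code=0))
        # with sex flipped the sex main effect changes sign at group = 0
        assert f1["biomarker_change:sex"]["estimate"] == pytest.approx(
            -f0["biomarker_change:sex"]["estimate"], rel=1e-6)
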