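"""Generator contracts: presets, determinism, structure, label closure."""

import numpy as np
import pandas as pd
import pytest

import taumem as tm
from taumem.synthetic import COHORT_COLUMNS, SCORE_RANGES, TRUTH_COLUMNS


class TestPresets:
    def test_table2_carries_printed_effects(self):
        eff = tm.preset_from_table("table2")
        assert eff.beta["biomarker_change:sex:group"] == -17.47
        assert eff.beta["biomarker_change"] == -19.97
        assert eff.tau00 == 0.12
        assert eff.sigma2 == 0.56

    def test_table3_mci_carries_printed_effects(self):
        eff = tm.preset_from_table("table3-mci")
        assert eff.beta["biomarker_change:sex"] == 10.17
        assert eff.beta["biomarker_change"] == -23.98
        assert eff.beta["sex"] == -0.10

    def test_null_zeroes_every_interaction(self):
        eff = tm.preset_from_table("null")
        for term, value in eff.beta.items():
            if ":" in term:
                assert value == 0.0
        assert eff.tau00 == tm.preset_from_table("table2").tau00

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="table3-mci"):
            tm.preset_from_table("table9")


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_visits": 1},
        {"age_sd": 0.0},
        {"innovation_sd_biomarker": -0.1},
        {"apoe_prev": 1.2},
        {"mode": "latent"},
        {"n_per_cell": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tm.CohortConfig(**kwargs)

    def test_unknown_cell_key_rejected(self):
        with pytest.raises(ValueError, match="unknown cell"):
            tm.CohortConfig(n_per_cell={("female", "dementia"): 5})

    def test_effects_require_exact_term_names(self):
        beta = dict(tm.preset_from_table("table2").beta)
        beta.pop("sex")
        with pytest.raises(ValueError, match="missing"):
            tm.TrueEffects(beta=beta, tau00=0.1, sigma2=0.5)
        with pytest.raises(ValueError, match="sigma2"):
            tm.TrueEffects(beta=tm.preset_from_table("table2").beta,
                           tau00=0.1, sigma2=0.0)


class TestCohortStructure:
    def test_same_seed_byte_identical(self, small_config, effects_table2,
                                      cohort_direct, tmp_path):
        again = tm.generate_cohort(small_config, effects_table2)
        pd.testing.assert_frame_equal(cohort_direct, again)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        tm.cohort_to_csv(cohort_direct, p1)
        tm.cohort_to_csv(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, small_config, effects_table2,
                                    cohort_direct):
        other = tm.generate_cohort(
            tm.CohortConfig(n_per_cell=30, seed=43), effects_table2)
        assert not cohort_direct.equals(other)

    def test_cell_counts_match_config(self, effects_table2):
        cells = {("female", "preclinical"): 7, ("male", "preclinical"): 11,
                 ("female", "MCI"): 5, ("male", "MCI"): 13}
        coh = tm.generate_cohort(
            tm.CohortConfig(n_per_cell=cells, seed=1), effects_table2)
        base = coh[coh.visit == 0]
        got = base.groupby(["sex", "group"]).size()
        for (s, g), n in cells.items():
            assert got.loc[(s, g)] == n

    def test_visits_gap_free_and_scores_in_range(self, cohort_direct):
        for _, grp in cohort_direct.groupby("pid"):
            assert list(grp.visit) == list(range(grp.visit.max() + 1))
        for test, (lo, hi) in SCORE_RANGES.items():
            vals = cohort_direct[test]
            assert vals.between(lo, hi).all(), test
        assert (cohort_direct.biomarker_ratio >= 0).all()

    def test_direct_mode_has_truth_raw_does_not(self, cohort_direct,
                                                cohort_raw):
        assert set(TRUTH_COLUMNS) <= set(cohort_direct.columns)
        assert not set(TRUTH_COLUMNS) & set(cohort_raw.columns)
        assert list(cohort_raw.columns) == list(COHORT_COLUMNS)

    def test_truth_variables_realize_the_declared_model(self, cohort_direct,
                                                        small_config,
                                                        effects_table2):
        """y - x'beta - b must be iid noise with variance sigma2."""
        df = cohort_direct[cohort_direct.visit >= 1]
        sex = (df.sex == "female").astype(float)
        grp = (df.group == "MCI").astype(float)
        b = effects_table2.beta
        xb = (b["intercept"] + b["biomarker_change"] * df.truth_u
              + b["sex"] * sex + b["group"] * grp
              + b["age_c"] * (df.age_baseline - small_config.age_mean)
              + b["edu_c"] * (df.education - small_config.edu_mean)
              + b["apoe4"] * df.apoe4.astype(float)
              + b["biomarker_change:sex"] * df.truth_u * sex
              + b["biomarker_change:group"] * df.truth_u * grp
              + b["sex:group"] * sex * grp
              + b["biomarker_change:sex:group"] * df.truth_u * sex * grp)
        eps = df.truth_y - xb - df.truth_b
        n = len(eps)
        assert abs(eps.mean()) < 4 * np.sqrt(effects_table2.sigma2 / n)
        assert eps.var(ddof=1) == pytest.approx(effects_table2.sigma2,
                                                rel=0.25)

    def test_null_preset_three_way_consistent_with_zero(self):
        eff = tm.preset_from_table("null")
        coh = tm.generate_cohort(
            tm.CohortConfig(n_per_cell=150, seed=9), eff)
        fit = tm.fit_lmm(tm.direct_model_frame(coh))
        row = fit["biomarker_change:sex:group"]
        assert abs(row["estimate"]) < 3 * row["se"]


class TestNormativeReference:
    def test_recovers_generating_coefficients(self, small_config):
        reference = tm.generate_normative_reference(small_config, n=20000)
        models = tm.fit_norms(reference)
        for test, truth in tm.NORMATIVE_TRUTH.items():
            m = models[test]
            assert m.coef_age == pytest.approx(truth["coef_age"], abs=0.05)
            assert m.coef_sex == pytest.approx(truth["coef_sex"], abs=0.3)
            assert m.coef_edu == pytest.approx(truth["coef_edu"], abs=0.05)
            assert m.residual_sd == pytest.approx(truth["residual_sd"],
                                                  rel=0.05)

    def test_self_normalization(self, reference, norms):
        for test in tm.STAGING_TESTS:
            z = tm.z_score(reference[test], reference.age, reference.sex,
                           reference.education, norms[test])
            assert abs(z.mean()) < 0.02
            assert z.std(ddof=1) == pytest.approx(1.0, abs=0.02)

    def test_zero_residual_sd_rejected(self, small_config):
        truth = {"tmt_a": dict(tm.NORMATIVE_TRUTH["tmt_a"],
                               residual_sd=0.0)}
        with pytest.raises(ValueError, match="residual_sd"):
            tm.generate_normative_reference(small_config, n=100, truth=truth)

    def test_reference_is_deterministic(self, small_config, reference):
        again = tm.generate_normative_reference(small_config, n=4000)
        pd.testing.assert_frame_equal(reference, again)


def test_cohort_csv_round_trip(cohort_raw, tmp_path):
    path = tmp_path / "cohort.csv"
    tm.cohort_to_csv(cohort_raw, path)
    back = tm.cohort_from_csv(path)
    assert list(back.columns) == list(COHORT_COLUMNS)
    assert back.pid.nunique() == cohort_raw.pid.nunique()


def test_cohort_csv_missing_column_rejected(cohort_raw, tmp_path):
    path = tmp_path / "bad.csv"
    cohort_raw.drop(columns=["tmt_a"]).to_csv(path, index=False)
    with pytest.raises(ValueError, match="tmt_a"):
        tm.cohort_from_csv(path)
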