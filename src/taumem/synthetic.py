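"""Synthetic longitudinal cohorts for the pTau181/Abeta42 -- memory-decline analysis.

The real study population (older adults staged as preclinical AD or MCI,
followed roughly annually with CSF draws and RAVLT testing) is access
restricted, so every downstream stage of the pipeline is exercised on
cohorts drawn from an explicit generative model:

* analysis-variable truth ("direct" mode): per-visit biomarker-change
  innovations ``u_it ~ N(0, innovation_sd^2)`` and memory-change values
  ``y_it = x_it' beta + b_i + eps_it`` with a participant random intercept
  ``b_i ~ N(0, tau00)`` and residual ``eps_it ~ N(0, sigma2)`` — exactly the
  random-intercept interaction model the estimator assumes, so fixed-effect
  recovery can be tested without attenuation;
* raw-series reconstruction ("raw" mode): first-order autoregressions whose
  innovations are those same change variables, so the full lagged-residual
  pipeline (staging -> composite -> change scores -> models) has to recover
  them itself.

Direct-mode output keeps the hidden truth columns (``truth_b``, ``truth_u``,
``truth_y``); raw mode emits only the observable series.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
import pandas as pd

FEMALE = "female"
MALE = "male"
PRECLINICAL = "preclinical"
MCI = "MCI"

SEXES = (FEMALE, MALE)
GROUPS = (PRECLINICAL, MCI)

#: Fixed-effect terms of the full three-way interaction model, in design order.
MODEL_TERMS = (
    "intercept",
    "biomarker_change",
    "sex",
    "group",
    "age_c",
    "edu_c",
    "apoe4",
    "biomarker_change:sex",
    "biomarker_change:group",
    "sex:group",
    "biomarker_change:sex:group",
)

#: The six staging tests, grouped three domains x two tests.
STAGING_TESTS = (
    "tmt_a",
    "tmt_b",
    "category_fluency",
    "boston_naming",
    "ravlt_delayed",
    "ravlt_recognition",
)

#: Timed tests score "lower is better"; everything else the reverse.
HIGHER_IS_BETTER = {
    "tmt_a": False,
    "tmt_b": False,
    "category_fluency": True,
    "boston_naming": True,
    "ravlt_delayed": True,
    "ravlt_recognition": True,
}

#: Admissible raw-score ranges used for clipping reconstructed scores.
SCORE_RANGES = {
    "tmt_a": (10.0, 300.0),
    "tmt_b": (20.0, 400.0),
    "category_fluency": (0.0, 60.0),
    "boston_naming": (0.0, 30.0),
    "ravlt_delayed": (0.0, 15.0),
    "ravlt_recognition": (0.0, 15.0),
    "ravlt_immediate": (0.0, 75.0),
}

#: Generating coefficients of the normative regressions (score on raw age,
#: sex indicator with female = 1, and years of education).  Magnitudes are
#: chosen to sit in the range of published regression-based norms for these
#: instruments in older adults; they are the ground truth that
#: :func:`fit_norms <taumem.norms.fit_norms>` must recover from a reference
#: sample.
NORMATIVE_TRUTH = {
    "tmt_a": {"intercept": 16.0, "coef_age": 0.45, "coef_sex": -1.0,
              "coef_edu": -0.50, "residual_sd": 8.0},
    "tmt_b": {"intercept": 40.0, "coef_age": 1.20, "coef_sex": -3.0,
              "coef_edu": -1.50, "residual_sd": 20.0},
    "category_fluency": {"intercept": 25.0, "coef_age": -0.12, "coef_sex": 1.5,
                         "coef_edu": 0.35, "residual_sd": 4.0},
    "boston_naming": {"intercept": 22.0, "coef_age": -0.05, "coef_sex": -0.5,
                      "coef_edu": 0.35, "residual_sd": 2.5},
    "ravlt_delayed": {"intercept": 15.0, "coef_age": -0.15, "coef_sex": 1.8,
                      "coef_edu": 0.20, "residual_sd": 3.2},
    "ravlt_recognition": {"intercept": 14.0, "coef_age": -0.04, "coef_sex": 0.7,
                          "coef_edu": 0.06, "residual_sd": 1.6},
}

#: Reconstruction scale of the two composite components: immediate-recall
#: (baseline mean, points per composite z) and delayed-recall points per
#: composite z.  The steps are deliberately smaller than the cross-sectional
#: score SDs so the bounded RAVLT scales (0-75 / 0-15) rarely saturate over
#: five visits of drift; saturation would truncate the reconstructed change
#: series.
_IMMEDIATE_SCALE = (30.0, 8.0)
_DELAYED_SCALE_SD = 1.8

#: Column order of the emitted long table.
COHORT_COLUMNS = (
    "pid", "visit", "sex", "group", "age_baseline", "education", "apoe4",
    "biomarker_ratio", "ravlt_immediate", "ravlt_delayed",
    "tmt_a", "tmt_b", "category_fluency", "boston_naming", "ravlt_recognition",
    "biomarker_positive", "dementia",
)
TRUTH_COLUMNS = ("truth_b", "truth_u", "truth_y")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``n_per_cell`` is either a single count applied to each of the four
    sex x group cells or a mapping ``{(sex, group): count}``; cells may be
    omitted (count 0) to build single-group cohorts.  Visits are annual and
    gap free; ``n_visits = 5`` gives a four-year follow-up matching the
    study's mean.  Demographic and biomarker defaults emulate the baseline
    descriptives of the cohort the analysis targets: age 74 +/- 6.5 y,
    education 16 +/- 2.7 y, APOE-e4 prevalence 0.57, baseline ratio
    0.044 +/- 0.028.
    """

    n_per_cell: int | Mapping[tuple[str, str], int] = 100
    n_visits: int = 5
    age_mean: float = 74.0
    age_sd: float = 6.5
    edu_mean: float = 16.0
    edu_sd: float = 2.7
    apoe_prev: float = 0.57
    ratio_baseline_mean: float = 0.044
    ratio_baseline_sd: float = 0.028
    ar_intercept: float = 0.0088
    ar_slope: float = 0.8
    innovation_sd_biomarker: float = 0.03
    female_memory_advantage: float = 0.6
    cutpoint: float = 0.025
    mode: str = "direct"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2: change scores need at "
                             "least two timepoints per participant")
        for name in ("age_sd", "edu_sd", "ratio_baseline_sd",
                     "innovation_sd_biomarker"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.apoe_prev <= 1.0:
            raise ValueError("apoe_prev must lie in [0, 1]")
        if self.mode not in ("direct", "raw"):
            raise ValueError("mode must be 'direct' or 'raw'")
        cells = self.cells()
        if any(n < 0 for n in cells.values()):
            raise ValueError("cell counts must be non-negative")
        if sum(cells.values()) == 0:
            raise ValueError("cohort is empty: all cell counts are zero")

    def cells(self) -> dict[tuple[str, str], int]:
        """Resolved ``{(sex, group): count}`` mapping over the four cells."""
        if isinstance(self.n_per_cell, int):
            return {(s, g): self.n_per_cell for s in SEXES for g in GROUPS}
        cells = {(s, g): 0 for s in SEXES for g in GROUPS}
        for key, n in dict(self.n_per_cell).items():
            sex, group = key
            if (sex, group) not in cells:
                raise ValueError(f"unknown cell {key!r}; sexes are {SEXES}, "
                                 f"groups are {GROUPS}")
            cells[(sex, group)] = int(n)
        return cells

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if not isinstance(d["n_per_cell"], int):
            d["n_per_cell"] = {f"{s}/{g}": n
                               for (s, g), n in self.cells().items()}
        return d


@dataclass(frozen=True)
class TrueEffects:
    """Generative fixed effects and variance components.

    ``beta`` maps each term of :data:`MODEL_TERMS` to its coefficient;
    ``tau00`` is the between-participant intercept variance and ``sigma2``
    the residual variance of the memory-change model.
    """

    beta: Mapping[str, float]
    tau00: float
    sigma2: float

    def __post_init__(self) -> None:
        missing = set(MODEL_TERMS) - set(self.beta)
        extra = set(self.beta) - set(MODEL_TERMS)
        if missing or extra:
            raise ValueError(
                f"beta must name exactly the model terms {MODEL_TERMS}; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}")
        if self.tau00 < 0:
            raise ValueError("tau00 must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    def ordered_beta(self) -> np.ndarray:
        return np.array([self.beta[t] for t in MODEL_TERMS], dtype=float)


_PRESETS: dict[str, TrueEffects] = {
    # Full-sample three-way interaction model (both diagnostic groups).
    "table2": TrueEffects(
        beta={
            "intercept": 0.75,
            "biomarker_change": -19.97,
            "sex": -0.32,
            "group": -0.84,
            "age_c": -0.01,
            "edu_c": 0.01,
            "apoe4": -0.11,
            "biomarker_change:sex": 8.05,
            "biomarker_change:group": 22.91,
            "sex:group": 1.05,
            "biomarker_change:sex:group": -17.47,
        },
        tau00=0.12, sigma2=0.56),
    # Stratified preclinical-AD model; group terms are inert (single group).
    "table3-preclinical": TrueEffects(
        beta={
            "intercept": 0.15,
            "biomarker_change": -9.10,
            "sex": -0.10,
            "group": 0.0,
            "age_c": -0.01,
            "edu_c": 0.02,
            "apoe4": -0.15,
            "biomarker_change:sex": -3.73,
            "biomarker_change:group": 0.0,
            "sex:group": 0.0,
            "biomarker_change:sex:group": 0.0,
        },
        tau00=0.05, sigma2=0.31),
    # Stratified MCI model; group terms inert.
    "table3-mci": TrueEffects(
        beta={
            "intercept": 0.07,
            "biomarker_change": -23.98,
            "sex": -0.10,
            "group": 0.0,
            "age_c": 0.0,
            "edu_c": -0.01,
            "apoe4": 0.04,
            "biomarker_change:sex": 10.17,
            "biomarker_change:group": 0.0,
            "sex:group": 0.0,
            "biomarker_change:sex:group": 0.0,
        },
        tau00=0.02, sigma2=0.10),
}
_PRESETS["null"] = TrueEffects(
    beta={t: (0.0 if ":" in t else _PRESETS["table2"].beta[t])
          for t in MODEL_TERMS},
    tau00=_PRESETS["table2"].tau00,
    sigma2=_PRESETS["table2"].sigma2)

#: Sex x group cell sizes of the study sample, usable as ``n_per_cell``.
STUDY_CELLS = {
    (FEMALE, PRECLINICAL): 69,
    (MALE, PRECLINICAL): 68,
    (FEMALE, MCI): 113,
    (MALE, MCI): 151,
}


def preset_from_table(name: str) -> TrueEffects:
    """Return the generative truth for one of the named presets.

    ``"table2"`` carries the full-model fixed effects and variance
    components, ``"table3-preclinical"`` / ``"table3-mci"`` the stratified
    per-group models, and ``"null"`` zeroes every interaction coefficient
    while keeping the full-model main effects and variance components (used
    for type-I-error calibration).
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: "
            f"{sorted(_PRESETS)}") from None


def _draw_staging_z(rng: np.random.Generator, n: int,
                    is_mci: np.ndarray) -> np.ndarray:
    """Baseline normative z-scores for the six staging tests.

    MCI participants get one randomly chosen domain with both tests well
    below the impairment cut (uniform on [-2.8, -1.5]); everyone's remaining
    tests are drawn from N(0.3, 0.6) floored at -0.8 so no spurious
    impairment can arise.  The 0.5-z margin on either side of the -1 cut
    absorbs score rounding and norm re-estimation noise, keeping generated
    labels recoverable by the staging stage.
    """
    z = rng.normal(0.3, 0.6, size=(n, 6))
    np.clip(z, -0.8, None, out=z)
    dom = rng.integers(0, 3, size=n)
    imp = rng.uniform(-2.8, -1.5, size=(n, 2))
    rows = np.flatnonzero(is_mci)
    for d in range(3):
        sel = rows[dom[rows] == d]
        z[sel, 2 * d:2 * d + 2] = imp[sel]
    return z


def _staging_raw_from_z(z: np.ndarray, age: np.ndarray, sex_ind: np.ndarray,
                        edu: np.ndarray) -> dict[str, np.ndarray]:
    """Invert the normative truth model: raw = predicted -/+ z * residual_sd."""
    out = {}
    for j, test in enumerate(STAGING_TESTS):
        t = NORMATIVE_TRUTH[test]
        pred = (t["intercept"] + t["coef_age"] * age
                + t["coef_sex"] * sex_ind + t["coef_edu"] * edu)
        sign = 1.0 if HIGHER_IS_BETTER[test] else -1.0
        raw = pred + sign * z[:, j] * t["residual_sd"]
        lo, hi = SCORE_RANGES[test]
        out[test] = np.clip(np.round(raw), lo, hi)
    return out


def generate_cohort(config: CohortConfig,
                    effects: TrueEffects) -> pd.DataFrame:
    """Generate one long-format cohort under ``config`` and ``effects``.

    One row per participant-visit, visits ``0 .. n_visits-1`` annual and gap
    free.  The memory-change and biomarker-change variables are generated
    first (the "analysis" variables); raw biomarker and RAVLT series are then
    reconstructed as AR(1) processes whose innovations are those variables.
    Identical ``(config, effects)`` (including the seed) yields a
    byte-identical table.
    """
    rng = np.random.default_rng(config.seed)
    cells = config.cells()
    T = config.n_visits

    sex_list, group_list = [], []
    for (s, g), n in cells.items():
        sex_list += [s] * n
        group_list += [g] * n
    sex = np.array(sex_list)
    group = np.array(group_list)
    N = sex.size
    sex_ind = (sex == FEMALE).astype(float)   # female = 1 by convention
    group_ind = (group == MCI).astype(float)  # MCI = 1

    age = np.clip(rng.normal(config.age_mean, config.age_sd, N), 55.0, 88.0)
    edu = np.clip(np.round(rng.normal(config.edu_mean, config.edu_sd, N)),
                  6.0, 20.0)
    apoe = (rng.random(N) < config.apoe_prev).astype(float)
    b = rng.normal(0.0, np.sqrt(effects.tau00), N)

    # Change variables for visits 1..T-1.
    u = rng.normal(0.0, config.innovation_sd_biomarker, size=(N, T - 1))
    eps = rng.normal(0.0, np.sqrt(effects.sigma2), size=(N, T - 1))
    beta = effects.beta
    age_c = age - config.age_mean
    edu_c = edu - config.edu_mean
    person_part = (beta["intercept"]
                   + beta["sex"] * sex_ind
                   + beta["group"] * group_ind
                   + beta["age_c"] * age_c
                   + beta["edu_c"] * edu_c
                   + beta["apoe4"] * apoe
                   + beta["sex:group"] * sex_ind * group_ind)
    u_slope = (beta["biomarker_change"]
               + beta["biomarker_change:sex"] * sex_ind
               + beta["biomarker_change:group"] * group_ind
               + beta["biomarker_change:sex:group"] * sex_ind * group_ind)
    y = person_part[:, None] + u_slope[:, None] * u + b[:, None] + eps

    # Raw biomarker ratio: AR(1) with the u innovations.
    ratio = np.empty((N, T))
    ratio[:, 0] = np.clip(
        rng.normal(config.ratio_baseline_mean, config.ratio_baseline_sd, N),
        1e-3, None)
    for t in range(1, T):
        ratio[:, t] = np.clip(
            config.ar_intercept + config.ar_slope * ratio[:, t - 1]
            + u[:, t - 1], 0.0, None)

    # Baseline staging tests (z pattern encodes the intended label).
    z6 = _draw_staging_z(rng, N, group_ind.astype(bool))
    staging0 = _staging_raw_from_z(z6, age, sex_ind, edu)

    # RAVLT series.  Delayed recall at baseline comes from its staging
    # z-score (the test serves both staging and the outcome composite);
    # immediate recall carries the female verbal-memory advantage.  Both
    # components then move in lock-step with the memory-change variable y.
    imm_mean, imm_sd = _IMMEDIATE_SCALE
    imm_z0 = (config.female_memory_advantage * sex_ind
              + 0.5 * z6[:, 4] + rng.normal(0.0, 0.8, N))
    imm = np.empty((N, T))
    dly = np.empty((N, T))
    imm[:, 0] = imm_mean + imm_sd * imm_z0
    dly[:, 0] = staging0["ravlt_delayed"]
    for t in range(1, T):
        imm[:, t] = imm[:, t - 1] + y[:, t - 1] * imm_sd
        dly[:, t] = dly[:, t - 1] + y[:, t - 1] * _DELAYED_SCALE_SD
    imm = np.clip(np.round(imm), *SCORE_RANGES["ravlt_immediate"])
    dly = np.clip(np.round(dly), *SCORE_RANGES["ravlt_delayed"])

    # Biomarker positivity: preclinical AD is biomarker positive by
    # definition; MCI positivity follows the baseline ratio with a small
    # extra PET-positive fraction.
    positive = ((group == PRECLINICAL)
                | (ratio[:, 0] >= config.cutpoint)
                | (rng.random(N) < 0.10))

    pid = np.array([f"P{i:04d}" for i in range(N)])
    rows = {
        "pid": np.repeat(pid, T),
        "visit": np.tile(np.arange(T), N),
        "sex": np.repeat(sex, T),
        "group": np.repeat(group, T),
        "age_baseline": np.repeat(np.round(age, 1), T),
        "education": np.repeat(edu, T).astype(int),
        "apoe4": np.repeat(apoe.astype(bool), T),
        "biomarker_ratio": np.round(ratio, 6).ravel(),
        "ravlt_immediate": imm.ravel().astype(int),
        "ravlt_delayed": dly.ravel().astype(int),
        "biomarker_positive": np.repeat(positive, T),
        "dementia": np.zeros(N * T, dtype=bool),
    }
    # Non-outcome staging tests are re-administered but essentially stable;
    # only the baseline values enter staging.
    for test in STAGING_TESTS:
        if test == "ravlt_delayed":
            continue
        series = np.repeat(staging0[test], T).reshape(N, T).astype(float)
        noise = rng.normal(0.0, 0.1 * NORMATIVE_TRUTH[test]["residual_sd"],
                           size=(N, T - 1))
        series[:, 1:] += noise
        lo, hi = SCORE_RANGES[test]
        rows[test] = np.clip(np.round(series), lo, hi).ravel().astype(int)

    df = pd.DataFrame(rows)[list(COHORT_COLUMNS)]
    if config.mode == "direct":
        df["truth_b"] = np.repeat(b, T)
        tu = np.full((N, T), np.nan)
        ty = np.full((N, T), np.nan)
        tu[:, 1:] = u
        ty[:, 1:] = y
        df["truth_u"] = tu.ravel()
        df["truth_y"] = ty.ravel()
    return df


def generate_normative_reference(config: CohortConfig, n: int = 5000,
                                 truth: Mapping[str, Mapping[str, float]]
                                 = NORMATIVE_TRUTH) -> pd.DataFrame:
    """Generate an unimpaired normative reference sample.

    Scores follow the linear generating model in ``truth`` exactly
    (score = intercept + age + sex + education effects + Gaussian residual),
    so norms fitted on this sample can be validated against the stored
    coefficients.  Scores are left unrounded; clipping to the admissible
    range is applied and matters only in the extreme tails.
    """
    for test, t in truth.items():
        if t["residual_sd"] <= 0:
            raise ValueError(f"residual_sd must be > 0 for {test!r}")
    rng = np.random.default_rng(config.seed + 1_000_003)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 55.0, 88.0)
    edu = np.clip(np.round(rng.normal(config.edu_mean, config.edu_sd, n)),
                  6.0, 20.0)
    sex = np.where(rng.random(n) < 0.5, FEMALE, MALE)
    sex_ind = (sex == FEMALE).astype(float)
    out = {
        "pid": [f"R{i:05d}" for i in range(n)],
        "age": np.round(age, 1),
        "sex": sex,
        "education": edu.astype(int),
    }
    for test, t in truth.items():
        pred = (t["intercept"] + t["coef_age"] * age
                + t["coef_sex"] * sex_ind + t["coef_edu"] * edu)
        raw = pred + rng.normal(0.0, t["residual_sd"], n)
        lo, hi = SCORE_RANGES.get(test, (-np.inf, np.inf))
        out[test] = np.round(np.clip(raw, lo, hi), 3)
    return pd.DataFrame(out)


def cohort_to_csv(df: pd.DataFrame, path, include_truth: bool = True) -> None:
    """Write a cohort in the documented fixed column order."""
    cols = [c for c in list(COHORT_COLUMNS) + list(TRUTH_COLUMNS)
            if c in df.columns and (include_truth or not c.startswith("truth_"))]
    df[cols].to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    return df
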