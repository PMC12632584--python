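"""Regression-based normative scoring.

Each neuropsychological test gets an ordinary-least-squares normative model
(score ~ age + sex + education) fitted on an unimpaired reference sample.
An individual's demographically corrected z-score is the signed standardized
residual, oriented so that lower z always means worse performance (timed
tests are flipped), and impairment is a z more than 1 SD below the
normative mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import FEMALE, HIGHER_IS_BETTER, STAGING_TESTS

_COVARIATES = ("age", "sex", "education")


@dataclass(frozen=True)
class NormativeModel:
    """Per-test normative regression: score ~ age + sex + education."""

    test_name: str
    intercept: float
    coef_age: float
    coef_sex: float
    coef_edu: float
    residual_sd: float
    higher_is_better: bool

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError(
                f"residual_sd must be > 0 for {self.test_name!r}")

    def predict(self, age, sex_ind, education):
        return (self.intercept + self.coef_age * np.asarray(age, float)
                + self.coef_sex * np.asarray(sex_ind, float)
                + self.coef_edu * np.asarray(education, float))


def _sex_indicator(sex, female_is_one: bool = True) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "OUS":
        ind = (s == FEMALE).astype(float)
    else:
        ind = s.astype(float)
    return ind if female_is_one else 1.0 - ind


def fit_norms(reference: pd.DataFrame,
              tests: Iterable[str] = STAGING_TESTS,
              higher_is_better: Mapping[str, bool] = HIGHER_IS_BETTER,
              ) -> dict[str, NormativeModel]:
    """Fit one OLS normative model per test on a reference sample.

    ``reference`` needs columns ``age``, ``sex``, ``education`` and one
    column per test.  The residual SD uses the degrees-of-freedom corrected
    root mean squared residual (n - 4 for the four regression parameters).
    Degenerate inputs — constant or collinear covariates, or a test with
    zero residual variance — are rejected with the offending test named.
    """
    tests = list(tests)
    missing = [c for c in _COVARIATES if c not in reference.columns]
    if missing:
        raise ValueError(f"reference sample lacks covariates: {missing}")
    n = len(reference)
    if n < 10:
        raise ValueError("reference sample must have at least 10 rows")

    X = np.column_stack([
        np.ones(n),
        reference["age"].to_numpy(float),
        _sex_indicator(reference["sex"].to_numpy()),
        reference["education"].to_numpy(float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "reference covariates are collinear or constant; cannot fit "
            "normative regressions")

    models: dict[str, NormativeModel] = {}
    for test in tests:
        if test not in reference.columns:
            raise ValueError(f"reference sample lacks test column {test!r}")
        y = reference[test].to_numpy(float)
        if np.any(~np.isfinite(y)):
            raise ValueError(f"non-finite scores in reference for {test!r}")
        fit = sm.OLS(y, X).fit()
        rsd = float(np.sqrt(fit.ssr / (n - X.shape[1])))
        if rsd < 1e-8 * max(1.0, float(np.abs(y).max())) \
                or not np.isfinite(rsd):
            raise ValueError(
                f"zero residual variance for {test!r}: scores are an exact "
                "function of the covariates")
        models[test] = NormativeModel(
            test_name=test,
            intercept=float(fit.params[0]),
            coef_age=float(fit.params[1]),
            coef_sex=float(fit.params[2]),
            coef_edu=float(fit.params[3]),
            residual_sd=rsd,
            higher_is_better=bool(higher_is_better[test]),
        )
    return models


def z_score(raw, age, sex, education, model: NormativeModel):
    """Demographically corrected z for a raw score.

    ``z = sign * (raw - predicted) / residual_sd`` with sign +1 when higher
    scores are better and -1 for timed tests, so lower z uniformly means
    worse performance.  Accepts scalars or aligned arrays.
    """
    for name, v in (("raw", raw), ("age", age), ("education", education)):
        if np.any(~np.isfinite(np.asarray(v, float))):
            raise ValueError(f"missing or non-finite {name}")
    if np.any(pd.isna(np.asarray(sex))):
        raise ValueError("missing sex")
    pred = model.predict(age, _sex_indicator(sex), education)
    sign = 1.0 if model.higher_is_better else -1.0
    z = sign * (np.asarray(raw, float) - pred) / model.residual_sd
    return float(z) if np.isscalar(raw) else z


def flag_impaired(z):
    """True iff z is strictly more than 1 SD below the normative mean."""
    z = np.asarray(z, float)
    if np.any(~np.isfinite(z)):
        raise ValueError("impairment flag requires finite z")
    out = z < -1.0
    return bool(out) if out.ndim == 0 else out


def norms_to_csv(models: Mapping[str, NormativeModel], path) -> None:
    rows = [{
        "test_name": m.test_name, "intercept": m.intercept,
        "coef_age": m.coef_age, "coef_sex": m.coef_sex,
        "coef_edu": m.coef_edu, "residual_sd": m.residual_sd,
        "higher_is_better": m.higher_is_better,
    } for m in models.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


def norms_from_csv(path) -> dict[str, NormativeModel]:
    df = pd.read_csv(path)
    return {
        r.test_name: NormativeModel(
            test_name=r.test_name, intercept=r.intercept,
            coef_age=r.coef_age, coef_sex=r.coef_sex, coef_edu=r.coef_edu,
            residual_sd=r.residual_sd,
            higher_is_better=bool(r.higher_is_better))
        for r in df.itertuples()
    }
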