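"""Random-intercept linear mixed models with sex x stage x biomarker interactions.

The outcome is the per-visit lagged-residual memory change; each participant
contributes one random intercept (variance tau00) on top of the residual
variance sigma2.  The full model carries the three-way
biomarker-change x sex x diagnostic-group interaction with all lower-order
terms plus baseline age (centered), education (centered) and APOE-e4; the
stratified per-group models keep the two-way biomarker-change x sex set.
Estimation is REML by default (ML available); inference is Wald:
CI = estimate +/- 1.96 SE, p from the normal reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from . import change as _change
from . import norms as _norms
from . import staging as _staging
from .synthetic import (MCI, MODEL_TERMS, CohortConfig, TrueEffects,
                        generate_cohort, preset_from_table)

FULL_TERMS: tuple[str, ...] = MODEL_TERMS
STRATIFIED_TERMS: tuple[str, ...] = (
    "intercept", "biomarker_change", "sex", "age_c", "edu_c", "apoe4",
    "biomarker_change:sex",
)

_BOUNDARY_TOL = 1e-8


@dataclass(frozen=True)
class LMMFit:
    """One fitted random-intercept model.

    ``params`` is a term-indexed frame with columns
    ``estimate, se, ci_low, ci_high, p``; ``tau00`` and ``sigma2`` are the
    between-participant and residual variances, ``icc`` their intraclass
    correlation.
    """

    params: pd.DataFrame
    tau00: float
    sigma2: float
    icc: float
    n_participants: int
    n_observations: int
    converged: bool
    method: str
    messages: tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, term: str) -> pd.Series:
        return self.params.loc[term]

    def to_frame(self) -> pd.DataFrame:
        """Serializable layout: one row per term plus a random-effects block."""
        out = self.params.reset_index(names="term")
        extra = pd.DataFrame({
            "term": ["sigma2", "tau00_id", "icc", "n_participants",
                     "n_observations"],
            "estimate": [self.sigma2, self.tau00, self.icc,
                         self.n_participants, self.n_observations],
        })
        return pd.concat([out, extra], ignore_index=True)


def icc(tau00: float, sigma2: float) -> float:
    """Intraclass correlation tau00 / (tau00 + sigma2)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if tau00 < 0:
        raise ValueError("tau00 must be >= 0")
    return tau00 / (tau00 + sigma2)


def build_design(data: pd.DataFrame,
                 terms: Sequence[str]) -> pd.DataFrame:
    """Design matrix for the named terms; ``a:b`` terms are products.

    Rank deficiency is rejected with the aliased columns named.
    """
    cols = {}
    for term in terms:
        if term == "intercept":
            cols[term] = np.ones(len(data))
        elif ":" in term:
            parts = term.split(":")
            v = np.ones(len(data))
            for p in parts:
                v = v * data[p].to_numpy(float)
            cols[term] = v
        else:
            cols[term] = data[term].to_numpy(float)
    X = pd.DataFrame(cols, index=data.index)
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, _, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        aliased = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; aliased terms: "
                         f"{aliased}")
    return X


def _wald_table(est: np.ndarray, se: np.ndarray,
                terms: Sequence[str]) -> pd.DataFrame:
    z = est / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "estimate": est, "se": se,
        "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
        "p": p,
    }, index=pd.Index(terms, name="term"))


def _gls_fixed(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
               tau00: float, sigma2: float):
    """Closed-form GLS with the random-intercept covariance held fixed.

    Per cluster V = tau00 J + sigma2 I, inverted by Woodbury:
    V^-1 = I/sigma2 - (tau00 / (sigma2 (sigma2 + m tau00))) J.
    """
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for g in np.unique(groups):
        idx = groups == g
        Xg, yg = X[idx], y[idx]
        m = Xg.shape[0]
        shrink = tau00 / (sigma2 * (sigma2 + m * tau00))
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        xtvx += Xg.T @ Xg / sigma2 - shrink * np.outer(sx, sx)
        xtvy += Xg.T @ yg / sigma2 - shrink * sx * sy
    cov = np.linalg.inv(xtvx)
    beta = cov @ xtvy
    return beta, np.sqrt(np.diag(cov))


def fit_lmm(data: pd.DataFrame, terms: Sequence[str] = FULL_TERMS,
            outcome: str = "memory_change", groups: str = "pid",
            reml: bool = True,
            fix_variance: tuple[float, float] | None = None) -> LMMFit:
    """Fit the random-intercept model of ``outcome`` on the named terms.

    With ``fix_variance=(tau00, sigma2)`` the variance components are held
    at the given values and the fixed effects come from the closed-form GLS
    solution instead of (RE)ML.  Non-convergence is surfaced through
    ``converged`` and ``messages``; a between-participant variance estimated
    at the zero boundary triggers a warning.
    """
    X = build_design(data, terms)
    y = data[outcome].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"non-finite values in outcome {outcome!r}")
    gvals = data[groups].to_numpy()
    msgs: list[str] = []

    if fix_variance is not None:
        tau00, sigma2 = fix_variance
        if sigma2 <= 0 or tau00 < 0:
            raise ValueError("fix_variance needs tau00 >= 0 and sigma2 > 0")
        beta, se = _gls_fixed(y, X.to_numpy(float), gvals, tau00, sigma2)
        return LMMFit(params=_wald_table(beta, se, list(terms)),
                      tau00=float(tau00), sigma2=float(sigma2),
                      icc=icc(tau00, sigma2),
                      n_participants=int(pd.unique(gvals).size),
                      n_observations=len(y), converged=True,
                      method="GLS-fixed")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(y, X, groups=gvals)
        result = model.fit(reml=reml)
    for w in caught:
        msgs.append(str(w.message))

    tau00 = float(np.asarray(result.cov_re)[0, 0])
    sigma2 = float(result.scale)
    est = np.asarray(result.fe_params, float)
    se = np.asarray(result.bse_fe, float)
    converged = bool(result.converged)
    if not converged:
        msgs.append("optimizer did not converge")
    if tau00 < _BOUNDARY_TOL:
        msg = ("between-participant variance estimated at the zero "
               "boundary; fixed effects coincide with OLS")
        warnings.warn(msg, stacklevel=2)
        msgs.append(msg)
    return LMMFit(params=_wald_table(est, se, list(X.columns)),
                  tau00=tau00, sigma2=sigma2, icc=icc(max(tau00, 0.0), sigma2),
                  n_participants=int(pd.unique(gvals).size),
                  n_observations=len(y), converged=converged,
                  method="REML" if reml else "ML",
                  messages=tuple(msgs))


def _sex_numeric(sex_values: np.ndarray, female: int = 1) -> np.ndarray:
    from .synthetic import FEMALE
    ind = (np.asarray(sex_values) == FEMALE).astype(float)
    return ind if female == 1 else 1.0 - ind


def assemble_model_frame(cohort: pd.DataFrame, change_table: pd.DataFrame,
                         labels: pd.DataFrame | None = None,
                         female_code: int = 1) -> pd.DataFrame:
    """Join change scores with participant-level model covariates.

    ``labels`` (a staging audit table) supplies the diagnostic group and
    positivity; without it the cohort's own ``group`` column is used.  Age
    and education are centered on the participants present in the frame.
    """
    base = cohort[cohort["visit"] == 0][
        ["pid", "sex", "group", "age_baseline", "education", "apoe4"]
    ].drop_duplicates("pid")
    frame = change_table.merge(base, on="pid", how="left")
    if labels is not None:
        lab = labels[["pid", "label", "biomarker_positive"]]
        frame = frame.merge(lab, on="pid", how="left")
        frame["group_label"] = frame["label"].map(
            {_staging.MCI_LABEL: MCI, _staging.PRECLINICAL_AD: "preclinical"})
    else:
        frame["group_label"] = frame["group"]
    frame["sex_label"] = frame["sex"]
    frame["sex"] = _sex_numeric(frame["sex"].to_numpy(), female_code)
    frame["group"] = (frame["group_label"] == MCI).astype(float)
    per_pid = frame.drop_duplicates("pid")
    frame["age_c"] = frame["age_baseline"] - per_pid["age_baseline"].mean()
    frame["edu_c"] = frame["education"] - per_pid["education"].mean()
    frame["apoe4"] = frame["apoe4"].astype(float)
    return frame


def direct_model_frame(cohort: pd.DataFrame,
                       female_code: int = 1) -> pd.DataFrame:
    """Model frame built from the hidden truth columns of a direct-mode cohort.

    Uses ``truth_u`` as the biomarker change and ``truth_y`` as the memory
    change, bypassing the lagged-residual reconstruction — this is the frame
    for estimator-recovery studies.
    """
    if "truth_u" not in cohort.columns:
        raise ValueError("cohort has no truth columns; generate it in "
                         "'direct' mode")
    obs = cohort[cohort["visit"] >= 1][
        ["pid", "visit", "truth_u", "truth_y"]
    ].rename(columns={"truth_u": "biomarker_change",
                      "truth_y": "memory_change"})
    return assemble_model_frame(cohort, obs, labels=None,
                                female_code=female_code)


def _stratum_fit(frame: pd.DataFrame, name: str, reml: bool) -> LMMFit:
    sexes = frame.drop_duplicates("pid")["sex_label"].unique()
    if len(sexes) < 2:
        raise ValueError(f"stratum {name!r} contains a single sex "
                         f"({sexes.tolist()}); the sex interaction is not "
                         "estimable")
    return fit_lmm(frame, STRATIFIED_TERMS, reml=reml)


@dataclass
class AnalysisResult:
    """Bundle of the four model fits plus pipeline audit artefacts."""

    fits: dict[str, LMMFit]
    staging: pd.DataFrame
    change_table: pd.DataFrame
    model_frame: pd.DataFrame
    metadata: dict


def run_full_analysis(cohort: pd.DataFrame,
                      norms: Mapping[str, _norms.NormativeModel] | None = None,
                      reference: pd.DataFrame | None = None,
                      cutpoint: float = _staging.DEFAULT_CUTPOINT,
                      female_code: int = 1,
                      reml: bool = True) -> AnalysisResult:
    """Run staging -> composite -> change scores -> the four model fits.

    Norms are fitted on ``reference`` if not supplied directly (they are
    never fitted on the analytic cohort itself).  Participants staged
    biomarker-negative CN or excluded for dementia leave the analytic
    sample.  Fits: full three-way model, the two stratified models, and the
    sensitivity model restricting MCI to biomarker-positive participants.
    """
    if norms is None:
        if reference is None:
            raise ValueError("supply fitted norms or a normative reference "
                             "sample")
        norms = _norms.fit_norms(reference)

    def _stage(stage_name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}"
                               ) from exc

    staged = _stage("staging", _staging.stage_baseline, cohort, norms,
                    cutpoint)
    keep = staged.loc[staged["label"].isin(
        [_staging.MCI_LABEL, _staging.PRECLINICAL_AD]), "pid"]
    if keep.empty:
        raise ValueError("no analysis groups: staging left no preclinical-AD "
                         "or MCI participants")
    analytic = cohort[cohort["pid"].isin(set(keep))]

    stdz = _stage("standardization", _change.baseline_standardization,
                  analytic)
    table, logs = _stage("change_scores", _change.build_change_table,
                         analytic, stdz)
    frame = _stage("model_frame", assemble_model_frame, analytic, table,
                   staged, female_code)

    fits: dict[str, LMMFit] = {}
    fits["full"] = _stage("model_full", fit_lmm, frame, FULL_TERMS, reml=reml)
    pre = frame[frame["group_label"] == "preclinical"]
    mci = frame[frame["group_label"] == MCI]
    fits["preclinical"] = _stage("model_preclinical", _stratum_fit, pre,
                                 "preclinical", reml)
    fits["mci"] = _stage("model_mci", _stratum_fit, mci, "mci", reml)
    sens = mci[mci["biomarker_positive"].astype(bool)]
    fits["sensitivity"] = _stage("model_sensitivity", _stratum_fit, sens,
                                 "sensitivity", reml)

    meta = {
        "cutpoint": cutpoint,
        "sex_coding": {"female": female_code, "male": 1 - female_code},
        "group_coding": {"MCI": 1, "preclinical": 0},
        "estimation": "REML" if reml else "ML",
        "standardization": {
            "immediate_mean": stdz.immediate_mean,
            "immediate_sd": stdz.immediate_sd,
            "delayed_mean": stdz.delayed_mean,
            "delayed_sd": stdz.delayed_sd,
        },
        "n_staged": int(len(staged)),
        "n_analytic_participants": int(keep.size),
        "n_by_model": {k: v.n_participants for k, v in fits.items()},
        "change_score_logs": logs,
        "label_counts": staged["label"].value_counts().to_dict(),
    }
    return AnalysisResult(fits=fits, staging=staged, change_table=table,
                          model_frame=frame, metadata=meta)


def recovery_study(effects: TrueEffects | str,
                   cells: Mapping[tuple[str, str], int] | int,
                   n_visits: int = 5, replicates: int = 200,
                   seed: int = 0, model: str = "full",
                   config_kwargs: Mapping | None = None) -> pd.DataFrame:
    """Monte-Carlo fixed-effect recovery on direct-mode cohorts.

    Generates ``replicates`` independent cohorts under the given generative
    truth, fits the requested model (``"full"`` or ``"stratified"``) to the
    hidden analysis variables of each, and summarizes per term: generative
    truth, replicate-mean estimate, bias, Monte-Carlo SE of the mean,
    empirical 95%-CI coverage of the truth, and the Wald rejection rate at
    alpha = .05.
    """
    if isinstance(effects, str):
        effects = preset_from_table(effects)
    terms = FULL_TERMS if model == "full" else STRATIFIED_TERMS
    base_rng = np.random.default_rng(seed)
    rows = {t: [] for t in terms}
    cover = {t: 0 for t in terms}
    reject = {t: 0 for t in terms}
    ci_width = {t: [] for t in terms}
    kw = dict(config_kwargs or {})
    for _ in range(replicates):
        rep_seed = int(base_rng.integers(2**31 - 1))
        config = CohortConfig(n_per_cell=dict(cells) if not
                              isinstance(cells, int) else cells,
                              n_visits=n_visits, mode="direct",
                              seed=rep_seed, **kw)
        frame = direct_model_frame(generate_cohort(config, effects))
        fit = fit_lmm(frame, terms)
        for t in terms:
            r = fit[t]
            rows[t].append(r["estimate"])
            truth = effects.beta[t]
            if r["ci_low"] <= truth <= r["ci_high"]:
                cover[t] += 1
            if r["p"] < 0.05:
                reject[t] += 1
            ci_width[t].append(r["ci_high"] - r["ci_low"])
    out = []
    for t in terms:
        est = np.asarray(rows[t])
        out.append({
            "term": t,
            "truth": effects.beta[t],
            "mean_estimate": est.mean(),
            "bias": est.mean() - effects.beta[t],
            "sd_estimate": est.std(ddof=1),
            "mc_se": est.std(ddof=1) / np.sqrt(replicates),
            "ci_coverage": cover[t] / replicates,
            "reject_rate": reject[t] / replicates,
            "mean_ci_width": float(np.mean(ci_width[t])),
        })
    return pd.DataFrame(out).set_index("term")
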