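"""Verbal-memory composite and lagged-residual change scores.

The memory outcome is the mean of z-scored RAVLT Immediate (0-75) and
Delayed (0-15) Recall, standardized against the baseline analytic sample by
default so longitudinal change stays in baseline SD units.  Change in both
the composite and the CSF pTau181/Abeta42 ratio is measured as lagged
residuals: one pooled OLS regression of each variable's value at visit t on
its value at visit t-1 across all adjacent person-visit pairs, with the
residual — the deviation from the level-predicted value — assigned to
visit t.  Residualizing on the prior level removes the autocorrelation a
simple difference would retain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SCORE_RANGES


@dataclass(frozen=True)
class Standardization:
    """Mean/SD pairs used to z-score the two composite components."""

    immediate_mean: float
    immediate_sd: float
    delayed_mean: float
    delayed_sd: float

    def __post_init__(self) -> None:
        if self.immediate_sd <= 0 or self.delayed_sd <= 0:
            raise ValueError("standardization SDs must be > 0")


def baseline_standardization(cohort: pd.DataFrame) -> Standardization:
    """Component means/SDs from the baseline visits of the supplied sample."""
    base = cohort[cohort["visit"] == 0]
    imm = base["ravlt_immediate"].to_numpy(float)
    dly = base["ravlt_delayed"].to_numpy(float)
    sd_i, sd_d = imm.std(ddof=1), dly.std(ddof=1)
    if sd_i <= 0 or sd_d <= 0:
        raise ValueError("baseline sample has zero variance in a RAVLT "
                         "component; cannot standardize")
    return Standardization(imm.mean(), sd_i, dly.mean(), sd_d)


def memory_composite(immediate, delayed, standardization: Standardization):
    """Average of the two component z-scores; scalar or vectorized.

    Both components must be present and within range; a missing component
    yields a missing composite (propagated as NaN in the vectorized case,
    rejected for scalars).
    """
    imm = np.asarray(immediate, float)
    dly = np.asarray(delayed, float)
    scalar = imm.ndim == 0
    if scalar and (np.isnan(imm) or np.isnan(dly)):
        raise ValueError("both composite components must be present")
    lo_i, hi_i = SCORE_RANGES["ravlt_immediate"]
    lo_d, hi_d = SCORE_RANGES["ravlt_delayed"]
    with np.errstate(invalid="ignore"):
        bad = ((imm < lo_i) | (imm > hi_i) | (dly < lo_d) | (dly > hi_d))
    if np.any(bad):
        raise ValueError("RAVLT score out of admissible range "
                         f"(immediate {lo_i:.0f}-{hi_i:.0f}, "
                         f"delayed {lo_d:.0f}-{hi_d:.0f})")
    s = standardization
    z = ((imm - s.immediate_mean) / s.immediate_sd
         + (dly - s.delayed_mean) / s.delayed_sd) / 2.0
    return float(z) if scalar else z


def composite_table(cohort: pd.DataFrame,
                    standardization: Standardization | None = None,
                    ) -> pd.DataFrame:
    """Per-visit composite for a long cohort (pid, visit, memory_composite)."""
    if standardization is None:
        standardization = baseline_standardization(cohort)
    comp = memory_composite(cohort["ravlt_immediate"].to_numpy(float),
                            cohort["ravlt_delayed"].to_numpy(float),
                            standardization)
    return pd.DataFrame({
        "pid": cohort["pid"].to_numpy(),
        "visit": cohort["visit"].to_numpy(),
        "memory_composite": comp,
    })


def lagged_residuals(series: pd.DataFrame, value_col: str,
                     pid_col: str = "pid", visit_col: str = "visit",
                     ) -> tuple[pd.DataFrame, dict]:
    """Pooled lag-1 residual change scores for one variable.

    Pairs each visit t >= 1 with the participant's visit t-1 (strictly
    adjacent; pairs straddling a missing visit or a missing value are
    dropped and counted), fits a single OLS of value_t on value_{t-1} pooled
    over all pairs, and returns the residuals assigned to visit t together
    with a log dict (slope, intercept, pair counts).
    """
    df = (series[[pid_col, visit_col, value_col]]
          .sort_values([pid_col, visit_col], kind="mergesort")
          .reset_index(drop=True))
    prev_val = df.groupby(pid_col, sort=False)[value_col].shift(1)
    prev_vis = df.groupby(pid_col, sort=False)[visit_col].shift(1)
    adjacent = prev_vis == df[visit_col] - 1
    usable = adjacent & df[value_col].notna() & prev_val.notna()
    n_candidate = int((df.groupby(pid_col, sort=False)[visit_col].cumcount() > 0).sum())
    n_used = int(usable.sum())
    if n_used < 3:
        raise ValueError("need at least 3 usable (t-1, t) pairs to fit the "
                         "lag regression")
    x = prev_val[usable].to_numpy(float)
    y = df.loc[usable, value_col].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError(f"lagged predictor for {value_col!r} is constant; "
                         "lag-regression slope is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    out = pd.DataFrame({
        "pid": df.loc[usable, pid_col].to_numpy(),
        "visit": df.loc[usable, visit_col].to_numpy(),
        f"{value_col}_change": resid,
    })
    log = {"variable": value_col, "slope": float(slope),
           "intercept": float(intercept), "n_pairs_used": n_used,
           "n_pairs_dropped": n_candidate - n_used}
    return out, log


def build_change_table(cohort: pd.DataFrame,
                       standardization: Standardization | None = None,
                       ) -> tuple[pd.DataFrame, dict]:
    """ChangeTable (pid, visit, biomarker_change, memory_change) plus logs.

    The biomarker change is the lagged residual of the raw CSF ratio; the
    memory change is the lagged residual of the per-visit composite.
    """
    comp = composite_table(cohort, standardization)
    bio, log_b = lagged_residuals(
        cohort.rename(columns={"biomarker_ratio": "biomarker"}),
        "biomarker")
    mem, log_m = lagged_residuals(
        comp.rename(columns={"memory_composite": "memory"}), "memory")
    table = bio.merge(mem, on=["pid", "visit"], how="inner")
    table = table.rename(columns={"biomarker_change": "biomarker_change",
                                  "memory_change": "memory_change"})
    table.columns = ["pid", "visit", "biomarker_change", "memory_change"]
    return table, {"biomarker": log_b, "memory": log_m}


def simple_differences(series: pd.DataFrame, value_col: str,
                       pid_col: str = "pid", visit_col: str = "visit",
                       ) -> pd.DataFrame:
    """Adjacent-visit simple differences, for comparison with lagged residuals."""
    df = (series[[pid_col, visit_col, value_col]]
          .sort_values([pid_col, visit_col], kind="mergesort"))
    prev_val = df.groupby(pid_col, sort=False)[value_col].shift(1)
    prev_vis = df.groupby(pid_col, sort=False)[visit_col].shift(1)
    usable = (prev_vis == df[visit_col] - 1) & df[value_col].notna() \
        & prev_val.notna()
    return pd.DataFrame({
        "pid": df.loc[usable, pid_col].to_numpy(),
        "visit": df.loc[usable, visit_col].to_numpy(),
        f"{value_col}_diff": (df.loc[usable, value_col] - prev_val[usable]
                              ).to_numpy(float),
    })
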