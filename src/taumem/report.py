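"""Baseline descriptives and the deterministic report bundle.

Baseline sex comparisons use Welch's unequal-variance t-test for continuous
variables and Pearson's chi-square for categorical ones; the report bundle
mirrors the analysis output as plain CSV tables plus a run-metadata file
embedding seed, configuration hash and software versions.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .models import AnalysisResult
from .synthetic import FEMALE, MALE

_MODEL_FILES = {
    "full": "model_full.csv",
    "preclinical": "model_preclinical.csv",
    "mci": "model_mci.csv",
    "sensitivity": "model_sensitivity.csv",
}


def _welch_row(name, female, male, equal_var=False):
    f = np.asarray(female, float)
    m = np.asarray(male, float)
    if f.var(ddof=1) == 0 and m.var(ddof=1) == 0:
        # both groups constant: no sampling variability to test against
        stat = 0.0 if f.mean() == m.mean() else np.inf * np.sign(
            f.mean() - m.mean())
        p = 1.0 if f.mean() == m.mean() else 0.0
    else:
        stat, p = scipy.stats.ttest_ind(f, m, equal_var=equal_var)
    return {
        "variable": name, "test": "welch_t" if not equal_var else "pooled_t",
        "female_summary": f"{np.mean(female):.3f} ({np.std(female, ddof=1):.3f})",
        "male_summary": f"{np.mean(male):.3f} ({np.std(male, ddof=1):.3f})",
        "statistic": float(stat), "p": float(p),
        "n_female": len(female), "n_male": len(male),
    }


def _chi2_row(name, female_bool, male_bool):
    table = np.array([
        [np.sum(female_bool), len(female_bool) - np.sum(female_bool)],
        [np.sum(male_bool), len(male_bool) - np.sum(male_bool)],
    ])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        # a category absent in the whole sample: no association testable
        warnings.warn(f"{name}: degenerate 2x2 table (empty margin); "
                      "reporting chi-square 0, p = 1", stacklevel=3)
        stat, p = 0.0, 1.0
    else:
        correction = False
        if np.any(table == 0):
            warnings.warn(f"{name}: zero cell in the 2x2 table; applying "
                          "the Yates continuity correction", stacklevel=3)
            correction = True
        stat, p, _, _ = scipy.stats.chi2_contingency(table,
                                                     correction=correction)
    nf, nm = len(female_bool), len(male_bool)
    return {
        "variable": name, "test": "chi_square",
        "female_summary": f"{table[0, 0]} ({100 * table[0, 0] / nf:.1f}%)",
        "male_summary": f"{table[1, 0]} ({100 * table[1, 0] / nm:.1f}%)",
        "statistic": float(stat), "p": float(p),
        "n_female": nf, "n_male": nm,
    }


def baseline_table(cohort: pd.DataFrame, staged: pd.DataFrame,
                   change_table: pd.DataFrame | None = None,
                   composite: pd.DataFrame | None = None,
                   equal_var: bool = False) -> pd.DataFrame:
    """Baseline sex comparisons over the staged analytic sample.

    Covers age, education, APOE-e4, diagnostic group, follow-up duration,
    baseline ratio and (when supplied) baseline composite and mean change
    scores.  Continuous variables get a Welch t-test (pooled-variance
    optional), categorical ones a Pearson chi-square.
    """
    from .staging import MCI_LABEL, PRECLINICAL_AD

    keep = staged[staged["label"].isin([MCI_LABEL, PRECLINICAL_AD])]
    base = cohort[cohort["visit"] == 0].merge(
        keep[["pid", "label"]], on="pid")
    if base["sex"].isna().any():
        raise ValueError("baseline comparison requires non-missing sex")
    f = base[base["sex"] == FEMALE]
    m = base[base["sex"] == MALE]
    followup = (cohort.groupby("pid")["visit"].max().rename("followup_years")
                .reset_index().merge(base[["pid", "sex"]], on="pid"))

    rows = [
        _welch_row("age_baseline", f["age_baseline"], m["age_baseline"],
                   equal_var),
        _welch_row("education", f["education"], m["education"], equal_var),
        _chi2_row("apoe4", f["apoe4"].to_numpy(bool),
                  m["apoe4"].to_numpy(bool)),
        _chi2_row("diagnostic_group_mci",
                  (f["label"] == MCI_LABEL).to_numpy(),
                  (m["label"] == MCI_LABEL).to_numpy()),
        _welch_row("followup_years",
                   followup.loc[followup["sex"] == FEMALE, "followup_years"],
                   followup.loc[followup["sex"] == MALE, "followup_years"],
                   equal_var),
        _welch_row("biomarker_ratio_baseline", f["biomarker_ratio"],
                   m["biomarker_ratio"], equal_var),
    ]
    if composite is not None:
        cb = composite[composite["visit"] == 0].merge(
            base[["pid", "sex"]], on="pid")
        rows.append(_welch_row(
            "memory_composite_baseline",
            cb.loc[cb["sex"] == FEMALE, "memory_composite"],
            cb.loc[cb["sex"] == MALE, "memory_composite"], equal_var))
    if change_table is not None:
        cc = (change_table.groupby("pid")[["biomarker_change",
                                           "memory_change"]].mean()
              .reset_index().merge(base[["pid", "sex"]], on="pid"))
        for col in ("biomarker_change", "memory_change"):
            rows.append(_welch_row(
                f"mean_{col}",
                cc.loc[cc["sex"] == FEMALE, col],
                cc.loc[cc["sex"] == MALE, col], equal_var))
    return pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_report(outdir, result: AnalysisResult | None,
                 baseline: pd.DataFrame | None, config: dict,
                 log: dict | None = None) -> Path:
    """Write the report bundle: per-model CSVs, baseline table, metadata.

    Output is deterministic for identical inputs (no timestamps in table
    bodies).  Missing pieces are marked "not run" in the summary rather
    than failing.
    """
    import statsmodels

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["pTau181/Abeta42 change x sex x stage analysis report",
             "=" * 52, ""]

    if baseline is not None:
        baseline.to_csv(outdir / "baseline.csv", index=False)
        lines.append(f"Baseline comparisons: {len(baseline)} variables "
                     "(baseline.csv)")
    else:
        lines.append("Baseline comparisons: not run")

    for key, fname in _MODEL_FILES.items():
        if result is not None and key in result.fits:
            fit = result.fits[key]
            fit.to_frame().to_csv(outdir / fname, index=False)
            lines.append(
                f"Model {key!r}: N={fit.n_participants} participants, "
                f"{fit.n_observations} observations, sigma2={fit.sigma2:.3f}, "
                f"tau00={fit.tau00:.3f}, ICC={fit.icc:.2f}, "
                f"converged={fit.converged} ({fname})")
        else:
            lines.append(f"Model {key!r}: not run")

    meta = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "versions": {
            "taumem": "0.1.0",
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "metadata": result.metadata if result is not None else None,
        "log": log or {},
    }
    (outdir / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str))
    lines += ["", f"config_hash: {meta['config_hash']}"]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return outdir
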