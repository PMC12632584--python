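"""Actuarial (Jak/Bondi-style) baseline staging.

Six tests in three two-test domains — psychomotor speed/executive function
(TMT-A, TMT-B), language (category fluency, Boston Naming) and episodic
memory (RAVLT delayed recall, recognition).  A participant without dementia
is MCI if either (1) both tests of some domain are impaired, or (2) at
least one test is impaired in every domain; otherwise cognitively normal.
Cognitively normal participants who are AD-biomarker positive (CSF
pTau181/Abeta42 ratio at or above the cut-point, or any positive PET flag)
are preclinical AD; the rest are biomarker-negative CN and fall outside the
two analysis groups.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import norms as _norms
from .synthetic import STAGING_TESTS

DOMAINS: dict[str, tuple[str, str]] = {
    "speed_exec": ("tmt_a", "tmt_b"),
    "language": ("category_fluency", "boston_naming"),
    "memory": ("ravlt_delayed", "ravlt_recognition"),
}

CN_NEG = "CN_biomarker_negative"
PRECLINICAL_AD = "preclinical_AD"
MCI_LABEL = "MCI"
EXCLUDED = "excluded_dementia"

#: Default CSF pTau181/Abeta42 positivity cut-point.  The analysis is
#: threshold agnostic; this value is a configurable convention, not an
#: assay-validated cut, and a ratio exactly at the cut-point counts positive.
DEFAULT_CUTPOINT = 0.025


def classify_jak_bondi(impaired: Mapping[str, bool], dementia: bool = False,
                       domains: Mapping[str, Sequence[str]] = DOMAINS) -> str:
    """Classify one complete impairment profile as ``CN``/``MCI``/``excluded``.

    ``impaired`` must carry a boolean for every test of every domain; a
    partial profile is rejected rather than classified.
    """
    if dementia:
        return "excluded"
    flags = {}
    for dom, tests in domains.items():
        for t in tests:
            if t not in impaired or pd.isna(impaired[t]):
                raise ValueError(
                    f"incomplete impairment profile: missing flag for {t!r}")
            flags[t] = bool(impaired[t])
    within_domain = any(all(flags[t] for t in tests)
                        for tests in domains.values())
    across_domains = all(any(flags[t] for t in tests)
                         for tests in domains.values())
    return "MCI" if (within_domain or across_domains) else "CN"


def biomarker_positive(ratio=None, cutpoint: float = DEFAULT_CUTPOINT,
                       flags: Mapping[str, bool] | None = None) -> bool:
    """AD-biomarker positivity: ratio at/above cut-point OR any modality flag.

    ``flags`` may carry e.g. amyloid-PET / tau-PET booleans; missing (None)
    flags are ignored.  With neither a ratio nor any usable flag the call is
    rejected.
    """
    have_ratio = ratio is not None and not pd.isna(ratio)
    usable_flags = [bool(v) for v in (flags or {}).values()
                    if v is not None and not pd.isna(v)]
    if not have_ratio and not usable_flags:
        raise ValueError("biomarker positivity needs a ratio or at least "
                         "one modality flag")
    pos = False
    if have_ratio:
        if ratio < 0:
            raise ValueError("biomarker ratio must be >= 0")
        pos = ratio >= cutpoint
    return bool(pos or any(usable_flags))


def stage_baseline(cohort: pd.DataFrame,
                   norms: Mapping[str, _norms.NormativeModel],
                   cutpoint: float = DEFAULT_CUTPOINT,
                   domains: Mapping[str, Sequence[str]] = DOMAINS,
                   ) -> pd.DataFrame:
    """Stage every participant from baseline-visit data only.

    Returns a per-participant audit table: the six normative z-scores, the
    six impairment flags, both MCI criteria, the positivity inputs and the
    final label (``MCI`` / ``preclinical_AD`` / ``CN_biomarker_negative`` /
    ``excluded_dementia``).  ``domains`` may be overridden, e.g. to drop the
    memory domain for sensitivity analyses; classification then runs on the
    remaining domains.
    """
    base = cohort[cohort["visit"] == 0].copy()
    all_pids = cohort["pid"].unique()
    missing = sorted(set(all_pids) - set(base["pid"]))
    if missing:
        raise ValueError(
            f"{len(missing)} participants lack a baseline visit: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    if base["pid"].duplicated().any():
        raise ValueError("duplicate baseline rows for some participants")

    tests = [t for tests in domains.values() for t in tests]
    out = pd.DataFrame({"pid": base["pid"].to_numpy()})
    for t in tests:
        z = _norms.z_score(base[t].to_numpy(float),
                           base["age_baseline"].to_numpy(float),
                           base["sex"].to_numpy(),
                           base["education"].to_numpy(float),
                           norms[t])
        out[f"z_{t}"] = np.round(z, 4)
        out[f"impaired_{t}"] = _norms.flag_impaired(z)

    crit1 = np.zeros(len(base), dtype=bool)
    crit2 = np.ones(len(base), dtype=bool)
    for dom, dom_tests in domains.items():
        imp = np.column_stack([out[f"impaired_{t}"] for t in dom_tests])
        crit1 |= imp.all(axis=1)
        crit2 &= imp.any(axis=1)
    out["criterion1_within_domain"] = crit1
    out["criterion2_across_domains"] = crit2

    dementia = base["dementia"].to_numpy(bool)
    ratio = base["biomarker_ratio"].to_numpy(float)
    flag = (base["biomarker_positive"].to_numpy(bool)
            if "biomarker_positive" in base.columns
            else np.zeros(len(base), dtype=bool))
    positive = (ratio >= cutpoint) | flag
    out["biomarker_ratio_baseline"] = ratio
    out["biomarker_positive"] = positive

    is_mci = crit1 | crit2
    label = np.where(dementia, EXCLUDED,
                     np.where(is_mci, MCI_LABEL,
                              np.where(positive, PRECLINICAL_AD, CN_NEG)))
    out["label"] = label
    if not np.any(label != EXCLUDED):
        warnings.warn("all participants excluded for dementia: analytic "
                      "sample is empty", stacklevel=2)
    return out
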