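"""Simulate a synthetic longitudinal cohort and inspect its structure.

Generates ~400 older adults (two baseline groups: preclinical AD and MCI,
both sexes) followed over five annual visits, with CSF pTau181/Abeta42
ratios, RAVLT memory scores and the six staging tests.
"""

import taumem as tm

config = tm.CohortConfig(n_per_cell=tm.STUDY_CELLS, n_visits=5, seed=1)
effects = tm.preset_from_table("table2")
cohort = tm.generate_cohort(config, effects)

base = cohort[cohort.visit == 0]
print(f"{base.pid.nunique()} participants, {len(cohort)} visit rows")
print("\ncell sizes (sex x baseline group):")
print(base.groupby(["sex", "group"]).size().to_string())
print("\nbaseline descriptives:")
print(base[["age_baseline", "education", "biomarker_ratio"]]
      .describe().loc[["mean", "std"]].round(3).to_string())
print(f"APOE-e4 carriers: {base.apoe4.mean():.0%}")

# The 'direct' mode keeps the hidden generative change variables
# (truth_u = biomarker innovations, truth_y = memory change) so estimator
# behaviour can be checked against known truth; 'raw' mode withholds them.
print("\nhidden truth columns:", [c for c in cohort if c.startswith("truth")])
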