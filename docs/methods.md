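# Methods

This note documents the statistical machinery, the generative model behind
the synthetic cohorts, the defaults and the numerical choices, in the
package's own terms. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The analysis pipeline

The target analysis asks whether the within-person coupling between change
in the CSF pTau181/Aβ42 ratio and change in verbal memory differs by sex,
and whether that sex difference itself differs between the preclinical AD
and MCI stages. The pipeline is:

1. **Normative scoring** (`norms`). Per-test OLS of raw score on age, sex
   (female = 1) and years of education, fitted on an explicitly supplied
   unimpaired reference sample — never on the analytic cohort, which would
   make impairment rates circular. The residual SD uses the n − 4
   degrees-of-freedom correction. z-scores are signed so that lower always
   means worse; the Trail-Making tests (timed) are flipped. Impairment is
   z < −1 *strictly*: a score exactly 1 SD below the normative mean counts
   unimpaired.
2. **Actuarial staging** (`staging`). Three domains × two tests:
   psychomotor speed/executive (TMT-A, TMT-B), language (category fluency,
   Boston Naming), episodic memory (RAVLT delayed recall, recognition).
   Without dementia, MCI ⇔ both tests impaired in some domain OR ≥ one
   impaired test in every domain; otherwise cognitively normal, split into
   preclinical AD vs biomarker-negative CN by AD-biomarker positivity.
   Positivity is ratio ≥ cut-point OR any supplied PET modality flag
   (logical OR); a ratio exactly at the cut-point is positive. The default
   CSF-ratio cut-point 0.025 is a configurable convention, not an
   assay-validated threshold — the analysis itself is threshold-agnostic.
   Staging uses baseline data only and is a pure function of the flags, so
   it is order-independent and idempotent. Delayed recall serves both in
   staging and in the outcome composite; a `domains` override allows
   dropping the memory domain for sensitivity use.
3. **Change scores** (`change`). The memory composite is the mean of
   z-scored RAVLT Immediate (0–75) and Delayed (0–15) Recall; the
   standardization constants come from the baseline analytic sample and are
   reused at every visit so change stays in baseline-SD units. A missing
   component gives a missing composite (no single-component fallback).
   Change at visit t is the residual of one OLS of value_t on value_{t−1},
   pooled over all adjacent person-visit pairs per variable. Pooling is the
   only estimable choice at 2–5 visits per person (per-person lag
   regressions would have 1–4 points); a config switch for per-group
   pooling exists but pooled-across-groups is the default. Pairs straddling
   a missing visit are dropped (lag one means lag one), and residuals are
   not re-standardized before modelling.
4. **Mixed models** (`models`). Random-intercept LMMs fitted by REML
   (default; lme4's default likewise) through `statsmodels MixedLM`, with
   Wald CIs (±1.96 SE) and normal-reference p-values, matching symmetric
   printed intervals. Covariates: baseline age (centered on the analytic
   sample), education (centered), APOE-ε4. Four fits: full three-way model,
   two stratified models, and a sensitivity fit restricting MCI to
   biomarker-positive participants. A stratum containing one sex is an
   explicit error, not a silent term drop. Rank-deficient designs are
   rejected with the aliased terms named; τ00 estimates at the zero
   boundary produce a warning (fixed effects then coincide with OLS, which
   the tests verify to 1e-6). `fit_lmm(..., fix_variance=(τ00, σ²))`
   bypasses estimation and solves the closed-form GLS with the
   compound-symmetric covariance fixed — used for oracle comparisons.
   No multiple-testing adjustment is applied anywhere.
5. **Descriptives/report** (`report`). Baseline sex comparisons use
   Welch's t (robust default; pooled-variance optional) and Pearson's
   chi-square without continuity correction; a zero cell triggers the Yates
   correction with a warning, and an empty margin (a category absent from
   the whole sample) reports χ² = 0, p = 1 with a warning. The report
   bundle is deterministic: identical inputs give byte-identical tables.

## The synthetic cohort generator

The generator defines an explicit generative model for the analysis (none
is implied by the analysis itself) in two layers:

* **Direct mode.** Per visit t ≥ 1, biomarker innovations
  u_it ~ N(0, s²) and memory change
  y_it = x_it'β + b_i + ε_it, b_i ~ N(0, τ00), ε_it ~ N(0, σ²) — exactly
  the estimator's assumed model, with x the full interaction design. The
  hidden columns `truth_b`, `truth_u`, `truth_y` are retained, so
  estimator recovery can be tested without attenuation.
* **Raw mode.** Only observable series are emitted. The ratio follows an
  AR(1), ratio_t = c + φ·ratio_{t−1} + u_it (φ = 0.8, c chosen for a
  stationary mean of 0.044); the RAVLT components move in lock-step with
  y_it (immediate by 8 points and delayed by 1.8 points per composite-z
  unit), then are rounded and clipped to their admissible ranges. The
  pipeline must recover the innovations through its own lagged-residual
  step.

Generative-truth presets carry the fixed effects and variance components
of the full model ("table2"), the two stratified models
("table3-preclinical", "table3-mci"), and a "null" preset zeroing every
interaction for type-I-error calibration. For the stratified presets the
group-indexed coefficients are inert (single-group cohorts).

Default study conditions: four sex × group cells (69/68 preclinical,
113/151 MCI ≈ the study's 401), 5 annual gap-free visits (≈ 4-year
follow-up), age 74 ± 6.5 (clipped 55–88), education 16 ± 2.7, APOE-ε4
prevalence 0.57, baseline ratio 0.044 ± 0.028. The per-visit biomarker
innovation SD defaults to 0.03, matching the dispersion of the baseline
descriptives' change-score row; it is the scale against which the
β ≈ 10–24 coefficients (composite-z per unit ratio change) act. A
`female_memory_advantage` of 0.6 immediate-recall z-units yields a
baseline composite advantage of roughly 0.75 SD for females, which the
descriptives tests detect at the study n.

Baseline staging scores are drawn in z-space to encode the intended label:
MCI participants get one random domain with both tests in [−2.8, −1.5],
everyone else's tests are N(0.3, 0.6) floored at −0.8. The ±0.5-z margins
around the −1 cut absorb score rounding and norm re-estimation noise, so
the staging stage recovers generated labels essentially perfectly (≥ 99%
asserted). Non-outcome staging tests are near-constant across visits
(only baseline enters staging). Preclinical participants are biomarker
positive by construction; MCI positivity follows the baseline ratio plus
a 10% PET-positive remainder.

### What raw mode does and does not emulate

Raw-mode reconstruction is deliberately simple: bounded integer test
scores, a shared AR(1) backbone, no dropout, no practice effects, no assay
batch noise, no irregular visit schedules (CSF draws and testing are
assumed to co-occur). Two attenuation mechanisms are intrinsic and
documented rather than removed: (i) rounding/clipping of bounded scores
truncates extreme trajectories; (ii) the participant random intercept
leaks into the pooled lag regression (people with high b_i have
accumulated higher composite levels, so the lag slope partially absorbs
b), which shrinks the apparent τ00 and multiplies fixed effects by a
common factor < 1. Consequently raw-mode pipeline estimates are
attenuated but strongly correlated (r > 0.9, asserted) with the hidden
truth; quantitative recovery claims are always made in direct mode. The
translation steps (8 and 1.8 points per composite-z) are set below the
cross-sectional score SDs precisely to limit boundary saturation of the
0–75/0–15 scales.

## Numerical and design choices

* **Sex coding** is configurable (default female = 1). The direction of
  printed interaction terms depends on it; flipping the coding exactly
  negates the biomarker × sex interaction, which a test asserts.
* **Seeding.** One `numpy` Generator per cohort; replicate studies spawn
  per-replicate integer seeds (< 2³¹) from a base generator. Identical
  (config, effects, seed) gives byte-identical CSV output.
* **Degenerate inputs.** Constant/collinear normative covariates, zero
  residual variance (detected at a 1e-8 relative floor), constant lagged
  predictors, partial impairment profiles, cohorts without a baseline
  visit, empty analytic samples and single-sex strata are all explicit
  errors naming the offender; an all-dementia cohort warns and returns an
  empty analytic sample.
* **Monte-Carlo tolerances.** Recovery tests require replicate means
  within 2 Monte-Carlo SEs of truth (the MC SE is computed from the
  replicate SD, so the tolerance adapts to the replicate count); CI
  coverage is required within 3 binomial SEs of 0.95. Test-suite studies
  use 40–60 replicates and the type-I calibration 500 replicates at 200
  participants; `scripts/acceptance.py` uses 200 replicates at the full
  study cell sizes.
* **REML vs ML** changes variance components but leaves fixed effects
  essentially unchanged at these sizes (asserted at 0.02 absolute).

## Known limitations

* Wald inference has no small-sample (Kenward–Roger/Satterthwaite)
  correction; in small strata CI coverage can dip a few points below
  nominal. No random slopes, no Bayesian estimation.
* The preclinical stratum in this generator is cleaner than real cohort
  data (uniform visit counts, exact model innovations), so per-replicate
  CIs, while wide relative to the generative interaction, are narrower
  than the printed real-data intervals.
* Dementia progression, mortality, practice effects and assay drift are
  out of scope; dementia is an input flag used only for exclusion.
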