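# Methods

## Problem and approach

Degenerative ataxias — the polyglutamine spinocerebellar ataxias SCA1, SCA3
and SCA6 and the cerebellar type of multiple system atrophy (MSA-C) —
atrophy the cerebellum in disease-specific regional patterns. Because
patient groups are small and differ in how long and how severely affected
their members are, raw group comparisons of volumes confound disease effect
with disease stage and with normal ageing. The pipeline addresses this in
four steps:

1. **Head-size normalization.** Each raw regional volume (mm³) is divided
   by the subject's estimated total intracranial volume (eTIV), the simple
   ratio method. The seven analysis regions are the anterior lobe (lobules
   I–V), superior posterior lobe (VI–VII), inferior posterior lobe
   (VIII–IX), flocculonodular lobe (X), vermis, cerebellar white matter
   (cWM), and the aggregate cerebellar grey matter (cGM = the four
   hemispheric lobes + vermis, summed before z-scoring).
2. **Normative z-transformation.** For each region an OLS model of
   normalized volume on age is fitted on the healthy-control (HC) reference
   group (default linear in age; constant and quadratic forms available).
   Every subject's z-score is (observed − predicted(age)) / residual sd,
   where the residual sd uses denominator n − p. z = 0 is the expected HC
   mean at that age; z = −1 is one residual sd below it. Sex is not a
   covariate by default (an optional binary sex term exists); z-scores are
   computed for HC subjects too, which makes calibration testable.
3. **Trajectory regression.** Within each disease, each region's z-scores
   are regressed on ataxia duration (years since first gait disturbance)
   and, separately, on the SARA sum score (0–40), by OLS. The linear fit is
   the primary model: R² and the two-sided slope t-test p-value (equivalent
   to the Pearson-correlation test) are reported unadjusted, with a
   Benjamini–Hochberg column added as a clearly labelled extension.
   Quadratic and cubic fits are produced only as diagnostics
   (residual-vs-fitted, Q-Q, AIC); the package makes no automatic model
   choice, mirroring a visual-inspection workflow. Confidence bands are
   pointwise 95% intervals for the mean response on n − degree − 1 degrees
   of freedom.
4. **Anchors and profiles.** Trajectories are read out at shared anchor
   values of each covariate: 0 (extrapolation to onset / absence of ataxia)
   and the cohort-derived mean, computed as the **unweighted mean of the
   per-disease group means, rounded to the nearest integer**. With the
   default group summaries (durations 3.9/10.8/7.8/4.4 y, SARA
   12.1/12.8/13.3/17.2) this gives 7 years and 14 points; the
   subject-weighted mean would not (8.6 y), which is why the unweighted
   definition is used. Read-outs outside a disease's observed covariate
   range are computed but flagged as extrapolations — SARA 0 always is,
   since the inclusion rule requires SARA ≥ 3. Per-disease read-outs over
   the seven regions at one anchor form a radar profile; axis order is
   fixed across diseases, skipped regions are gaps (never zero), and by
   default the radial axis shows −z so that more atrophy points outward
   (a pure display convention, configurable).

## Cohort handling

Input is a subject-level CSV/TSV with a configurable column mapping
(YAML). Hard invariants (age > 0, eTIV > 0, 0 < volume < eTIV, SARA in
[0, 40], non-negative duration, no clinical scores on reference subjects)
reject individual rows with line-numbered diagnostics; duplicate subject
ids abort the read. The SARA upper bound 40 is the scale maximum.
Hemispheric volumes may arrive as left/right columns and are summed
(`combine_hemispheres`, idempotent). Inclusion filters: patients with
SARA < 3 (clinical ataxia cut-off) are excluded by default; an optional
duration cap (e.g. 30 y, for implausibly long MSA-C durations) is off by
default because it is a cohort-specific, post-hoc choice. Reference
subjects are never filtered. Numeric cells are parsed with correctly
rounded float conversion, so a written table re-reads bit-identically.

## Synthetic cohorts

`synthetic_data.generate_cohort` draws cohorts with the structure the
analysis assumes, with full ground-truth export. Defaults mirror a
multicentre cross-sectional ataxia cohort: 292 HC (age 63.5 ± 12.6) and
SCA1/SCA3/SCA6/MSA-C groups of n = 12/62/14/16 with the group-specific
age, duration and SARA moments listed in `_default_diseases`.

* **Clinical covariates.** Duration (≥ 0) and SARA (∈ [3, 40] by default)
  are truncated normals whose *truncated* mean and sd equal the configured
  targets — the underlying location/scale are solved numerically — joined
  by a Gaussian copula with correlation ρ = 0.5 (both covariates describe
  the same progression; no joint distribution is published, so ρ is a
  declared modelling choice). Moment matching by construction is what makes
  the generator's moments converge to the configured values; naive
  truncation would inflate, e.g., a 3.9 ± 3.3 duration mean by ~19%.
  Setting `sara_floor` below 3 injects sub-threshold patients to exercise
  the inclusion filter.
* **Volumes.** HC normalized volumes are region norms linear in age plus
  Gaussian residuals; the defaults (≈0.008–0.030 of eTIV, ~8% residual
  scatter, mild ageing decline) are population-plausible illustrative
  values — no raw-volume moments for the reference cohort are published.
  Patients get a target z from their disease's per-region trajectory line
  evaluated at the *driving covariate* (duration by default) plus z-noise
  (sd 0.8); volumes are recovered by inverting the z-definition through
  the true norm and multiplying by a drawn eTIV (1.55 ± 0.14 ×10⁶ mm³).
  The relation of z to the non-driving covariate is therefore emergent via
  the copula correlation rather than separately imposed.
* **Trajectory defaults** reproduce the qualitative pattern reported for
  these diseases — steepest decline in MSA-C, grey-matter-dominant atrophy
  with relatively spared cWM in SCA6, cWM involvement in SCA1/SCA3/MSA-C,
  and a few slight non-significant volume increases — and are documented
  as illustrative, not estimates.
* **cGM ground truth** is emergent: since cGM is summed before z-scoring
  and HC region residuals are independent, the true cGM residual sd is the
  quadrature sum of the constituents' sds and the implied cGM line is the
  sd-weighted mixture of the constituent lines
  (`GroundTruth.implied_cgm_line`).

What the generator does **not** emulate: scanner/site effects (the pipeline
has no harmonization stage), longitudinal visits, non-Gaussian residuals,
age-by-disease interactions in the norms, and the mobility-related
selection of less-affected patients at long durations. Passing recovery and
calibration tests therefore show the estimator is correct under its own
assumptions, not that real cohorts satisfy them.

## Numerical choices and edge cases

* All fits are OLS via statsmodels; residual sd and CI degrees of freedom
  use n − p. An independent normal-equations oracle in the test suite
  checks coefficients, R², and slope p-values to 1e-10 relative error.
* A constant response gives slope 0, R² = 0 and slope_p = 1 (handled
  explicitly; the degenerate standard error would otherwise produce noise).
* The low-level trajectory fit accepts n = degree + 1 (exact
  interpolation; R² = 1, slope_p undefined), while the pipeline skips
  disease groups with n < 4 per fit and records the skip in the manifest.
* z-score "exactness" (z = 0 at the predicted mean, −1 at one residual sd
  below) holds to machine precision; tests assert at 1e-12.
* Infeasible truncation targets (e.g. a SARA mean far below the floor with
  small sd) fail in the moment-matching solver with a generation error.
* Determinism: one `numpy` Generator seeded from the config; identical
  config + input produce byte-identical CSV outputs (figures may differ in
  embedded timestamps only).

## Problem sizes used in the checks

Monte-Carlo checks run 500 replicates at the default cohort size: slope-CI
coverage is evaluated for the n = 62 group (cWM vs duration) against the
generating slope, and HC calibration holds out 50 controls per replicate
against norms estimated on 292. Moment matching is checked at n = 5000.
Coverage uses z-scores from *estimated* norms, as in real use (the
estimated residual sd rescales slopes slightly, costing ~1–2 points of
coverage at these sizes); the noise-free convergence check z-scores through
the true norms, where the round-trip is exact by construction.

## Known limitations

* The ratio method of head-size correction is used by definition; the
  residual/covariate method is out of scope.
* No site harmonization, no mixed-effects or longitudinal modelling, no
  statistical test comparing radar profiles between diseases (the
  comparison is visual).
* The normative model is a global homoscedastic polynomial, not a
  GP/quantile normative model; extrapolation beyond the reference age
  range is flagged, not prevented.
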