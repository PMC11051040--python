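# Methods

## Growth model and estimation procedure

A Harris Line (HL) deposited when a bone had reached a fraction `x` of its
adult length is dated by a growth curve `age = y(x)`, with `x` expressed in
percent throughout (`(0, 100]`; the shipped coefficients are meaningless for
fractional ratios).  Three families are supported — linear `a·x + b`,
quadratic `a·x² + b·x + c`, exponential `a·e^(b·x) + c` — and the shipped
reference set contains all three fits for each of six strata (tibia/femur ×
male/female/unisex), with the lowest-AICc fit per stratum marked selected.
Male and unisex strata derive from 16-point source growth tables, female
strata from 14-point tables; these sizes are not printed alongside the
published statistics and were recovered by inverting the AICc − AIC
correction term (`infer_n_from_aicc_gap`), which yields integer solutions
(16, 14) consistently across rows.

The estimation chain for one line is:

1. growth apportionment: fraction `f` of total longitudinal growth at the
   line's end (defaults: tibia proximal 0.57 / distal 0.43; femur distal
   0.71 / proximal 0.29 — conventional reference constants, held in
   configuration, never hard-coded at call sites, and echoed in every
   output);
2. formation ratio: adults `x = 100·(L − d/f)/L`; non-adults
   `x = 100·(L − d/f) / L_adult` with `L_adult = 100·L / x(age_at_death)`
   the projected "would-be-adult" length;
3. age: `y(x)` from the stratum's selected curve, unisex forced for
   non-adults (immature skeletons cannot be reliably sexed); ages are
   reported to 0.01 years — the method's precision advantage over
   whole-year table lookup.

One published value is stored corrected: the tibia/female exponential AIC is
printed as 6.38 in the source table, which is impossible next to its own
AICc of −1.94 (AICc = AIC + a positive correction) and disagrees with
recomputation from the printed residual sum of squares (−6.39); the
constants file stores −6.38 with a note.  No other printed value is
altered.

## AIC convention

The published statistics carry no formula.  The Gaussian maximum-likelihood
form `AIC = n(ln 2π + ln(RSS/n) + 1) + 2K`, `K = coefficients + 1`,
`AICc = AIC + 2K(K+1)/(n − K − 1)`, reproduces all 18 published AIC/AICc
values within 0.02 given n = 16/14, and is locked in by oracle tests.  A
numerically zero RSS (below 1e−12) cannot be likelihood-scored; such fits
carry NaN criteria and are treated as the RSS → 0 limit (AIC → −∞) in
model selection, so a perfect interpolant is preferred, with ties broken by
fewer coefficients then lower RSS.

## Fitting

Levenberg–Marquardt least squares (scipy's `least_squares(method="lm")`)
minimises age-direction residuals, stopping at a relative cost change of
1e−10 within a bounded evaluation budget.  Exponential-plus-offset fits are
initialisation-sensitive: seeds come from a log-linearised fit of
`ln(y − c₀)` against `x` with `c₀ = min(y) − 1`, restarted from three
deterministic perturbations, keeping the best RSS.  Coefficient standard
errors come from the Jacobian at the optimum
(`cov = (JᵀJ)⁻¹ · RSS/(n − p)`).  Monte-Carlo calibration in the test suite
(500 replicates per family, σ = 0.1 y noise on 16-point tables) recovers
generating coefficients within 3 standard errors in ≥ 95 % of replicates.

## Curve domains, inversion, degenerate inputs

The validated ratio domain of each stratum runs from the selected curve's
age-zero crossing — floored at 30 %, below which the source tables provide
no coverage — up to 100 (the adult bone).  All three family fits of a
stratum share the stratum domain so flags are consistent.  Ratios outside
the domain still return an estimate, flagged `extrapolated`; negative
formula ages are clamped to 0 and flagged `clamped`.  Inversion
(`ratio_at_age`) uses closed forms per family (quadratic root selected
inside the domain; logarithmic form for the exponential) with a bracketed
root-finder fallback at 1e−9 tolerance on `x`; ages at or above the curve's
adult age return 100 flagged `adult`, ages below the domain raise an error.
Lookup-table emulation (`build_lookup`) tabulates a curve at 0.5- or
1.0-year steps from the last grid age covering the curve's minimum age
(obtained by raw-formula inversion when that grid age sits just below the
validated domain, mirroring printed growth tables that span early
childhood) to the last grid age at or below adult age; queries take the
nearest tabulated ratio, ties breaking toward the younger age.

## Method agreement

`bland_altman` summarises paired estimates by the mean difference, sample
(n−1) SD, limits of agreement at ±1.96 SD, and the maximum absolute
difference.  `equation_vs_lookup` draws formation ratios uniformly over
each selected curve's domain (200 per stratum by default, seeded) and
compares continuous readings against whole-year lookup.  Under these
conditions the mean difference is ≈ 0.01 y and the maximum ≈ 0.51 y —
inside the ≤ 0.1 y / ≤ 0.7 y envelope reported for this comparison on real
skeletal material — and both shrink as the table step is refined, because
the entire discrepancy is table rounding.

## Synthetic data

The generator produces the two validation inputs.  Growth tables: ratios on
an even grid over the curve domain, ages perturbed by Gaussian noise
(default σ = 0.1 y on 16 points).  Skeletal samples: by default 12 adult
individuals averaging 11 lines each (Poisson counts, ≈ 135 lines — the
scale of a small, well-preserved archaeological assemblage), adult tibial
lengths uniform on 34–40 cm, formation ages uniform over the curve's age
range, each line assigned a random end, distance computed by the forward
model `d = f·(L_current − L_adult·x(t)/100)`, and both measurements rounded
to 0.1 cm (the only default noise source; rounding 0 gives exact round
trips to within the 1e−9 inversion tolerance).  Non-adult bones are
truncated to the length expected at the individual's simulated age at
death; a line "formed" after death is skipped with a warning.  Ground-truth
formation ages go to a separate sidecar file the estimator never reads.

What the simulations do *not* emulate: real biological variation around the
population growth curve (early/late growth spurts, stunting, pathology),
age-at-death estimation error for non-adults, observer disagreement on
faint lines, and resorption of early lines by remodelling.  Passing
round-trip tests therefore demonstrates internal consistency of the
measurement → ratio → age chain at radiographic precision, not field
accuracy on skeletal material.

## Design choices and limitations

* The end-specific apportionment fractions and the exact ratio formula are
  reconstructed from the measurement logic (the primary description of the
  table-based method leaves them to its own source); both are configurable
  precisely because they are reconstructions.
* No epiphyseal-thickness correction is applied: `d` is measured to the
  nearest end of the complete bone.  A per-end offset hook can be emulated
  by adjusting distances upstream; the default is 0.
* The `end` field is mandatory and never inferred from `d < L/2`: mid-shaft
  lines are ambiguous and the observer's call is authoritative.
* With self-consistent inputs the estimated formation age can never exceed
  a non-adult's age at death (`x = x_now·(1 − d/(f·L)) ≤ x_now`), so the
  `inconsistent_chronology` flag fires only on corrupted inputs (e.g. a bad
  adult-length projection); it is a defensive guard, not an expected path.
* Unisex curves applied to adults of unknown sex are allowed but flagged
  (`unisex_curve`).
* The shipped curves describe mid-20th-century North American growth; for
  populations with different growth patterns, refit on a local growth table
  (`hlage fit`) and point the configuration at the resulting constants
  file.

## Problem sizes

Defaults were chosen at desk scale: 16-point growth tables, 500-replicate
recovery studies, 200 ratios per stratum (1200 pairs) for the agreement
analysis, and three-individual samples in round-trip tests.  All are
parameters of the public APIs and scale up directly.
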