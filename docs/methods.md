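# Methods

## The analysis

`romtraj` quantifies how active shoulder range of motion (ROM) evolves after
anatomic (aTSA) and reverse (rTSA) total shoulder arthroplasty, over three
phases, and screens for risk factors attached to the extremes of each phase.
Four ROM measures are analysed: active abduction, forward elevation and
external rotation (degrees), and the ordinal 0–6 internal-rotation (IR)
score.

**Rate of improvement (ROI).** For each patient, measure, and recovery-period
visit, ROI = (value − preoperative value) / months since surgery. Recovery
membership is decided by interval bins with nominal months {3, 6, 12, 24}
and edges (0, 4.5), [4.5, 9), [9, 18), [18, 30): midpoints between scheduled
visits, with the 2-year bin extended to 30 months so jittered late "2-year"
visits are kept. Rates are computed only at observed visits — no smoothing
or interpolation.

**Peak.** Each patient's peak per measure is the highest observed value in
the closed 24–36-month window ("2–3 years", read inclusively). Ties resolve
to the earliest visit, which keeps the decline denominator conservative.
Patients with no in-window visit for a measure have no peak and are excluded
from decline statistics for that measure.

**Rate of decline (ROD).** For each long-term visit (96+ months),
ROD = (peak value − value) / (visit time − peak time), stored
decline-positive. The denominator is time since the *peak visit* because the
decline is defined relative to the peak; a `time_base="surgery"` switch
divides by months since surgery instead. A patient still improving after
their peak has a negative ROD.

**Voting classification.** Cohort baselines are arithmetic mean rates per
cell — (prosthesis, measure, interval bin) for ROI, (prosthesis, measure)
for ROD — computed over all records, including the patient's own (no
leave-one-out). Each of a patient's rate records with a matching cell casts
one vote; the vote exceeds when the rate is *strictly* greater than the cell
mean. With exceedance fraction f: f > 2/3 → FAST, f < 1/3 → SLOW, otherwise
AVERAGE. Fractions are compared as exact rationals, so 4/6 sits exactly at
2/3 and is AVERAGE. Patients with fewer than `min_votes = 4` votes (one per
measure on average) are UNCLASSIFIED — some patients genuinely lack the
visits to establish a trend. One vote per (measure, visit) record is the
default unit; a `vote_unit="measure_mean"` switch averages per measure
first. For ROD, exceeding the cohort's mean decline labels the patient FAST.

**Risk screen.** Two comparisons: slow ROI vs. fast/average ROI, and fast
ROD vs. slow/average ROD, each fitted separately per prosthesis. Univariate:
a two-tailed unpaired t-test for continuous factors and Fisher's exact test
for binary factors. The t-test uses Welch degrees of freedom by default —
"unpaired t-test" does not commit to equal variances and Welch is the safer
default — with an `equal_var=True` pooled switch. Factors with univariate
p < 0.05 enter one multivariate logistic regression; there is no
multiple-testing adjustment and no imputation (complete case per factor).
The logistic fit is by iteratively reweighted least squares (IRLS): Newton
steps on the log-likelihood, convergence when the largest score component
drops below 1e-8 (within 100 iterations), covariance the inverse observed
information. Diverging coefficients (|β| > 15) raise a separation warning
and mark the fit non-converged; odds ratios are refused for non-converged
fits. Reported intervals are Wald: OR = exp(β), CI = exp(β ± 1.96·se) —
Wald intervals are what produce the very wide CIs characteristic of sparse
cells in this literature. Constant columns are dropped before the fit and a
multivariate model is only attempted with ≥ 10 complete cases.

**Reporting.** Group summary tables give mean ± SD per measure per class at
a chosen timepoint (preop, peak, or latest), with improvements computed
against preop at the patient level and then averaged. "Latest follow-up" is
each patient's maximum-time visit per measure, guarded to ≥ 96 months by
default (switchable) since long-term tables should not be diluted by
patients seen last at mid-term. The decline summary is peak mean − latest
mean per prosthesis and measure, rounded half-up to 1° for angles and to the
nearest half point for the IR score — the precision at which such declines
are conventionally quoted.

## The synthetic cohort generator

No patient-level data accompany the published cohort tables, so the
generator creates cohorts with the structure the analysis assumes; its
defaults are the published summary values where available.

The per-measure mean trajectory is

    mu(t) = P − m (P − R0) e^(−t/τ) − D (t/τ_d) e^(1 − t/τ_d)
            − s · max(0, t − t_dec)

with R0 the preoperative value, P the peak, τ = 4 months (recovery time
constant), τ_d = 3 months (dip trough time), t_dec = 36 months (decline
onset), s the late slope, and m a recovery multiplier (1 by default). The
dip depth D = c · max(0, R0 − θ) activates only above a preop threshold θ:
high-functioning shoulders transiently lose motion after surgery. Defaults:
c = 0.75 and θ = 90° for abduction/forward elevation; c = 0.25 and θ = 20°
for external rotation (its cohort mean is ~18°, so a 90° threshold would
never trigger); c = 0.05 per point above θ = 3 for the IR score. This
six-parameter form (saturating exponential + gamma-shaped dip + late linear
decline) reproduces the qualitative features of published recovery curves:
an early dip for high-preop patients, parallel improvement from 3 to 24
months, peak at 2–3 years, and slow late decline.

Preoperative values are drawn per prosthesis from the published means/SDs as
a two-stratum mixture: a latent "high-preop" class (prevalence 0.3) shifted
+1.6 pooled SD, the rest shifted down to keep the mixture mean at the
published value, with within-stratum SD chosen to keep the mixture SD near
the published SD. One latent draw moves all four measures together —
slow-recovery patients are high in every preop measure — and also multiplies
the recovery term by 0.7. The separation and multiplier are calibrated so
that an odds multiplier planted on the latent class (`class_probability`
effects) is realized nearly undiluted on the *classified* labels (median
attenuation < 15% at n = 600); weaker separation lets classification noise
eat planted effects, which would make the generator's effect contract
dishonest. Peaks are drawn weakly correlated with preop (ρ = 0.2): published
peak values are similar across recovery classes despite very different
preop ROM. Late decline slopes are truncated-normal, mean 0.08 °/month,
SD 0.05 (IR score scaled ×0.1 for the ordinal range). Revision surgery
applies a step loss of 30° (1.5 IR points) at a uniform random time in
40–100 months. Measurement noise is Gaussian (SD 5° for angles, 0.5 points
for the IR score before rounding); values are clamped to valid ranges after
noise so validation stays total, and IR scores are rounded half-up.

Visits follow the nominal schedule (preop, 3, 6, 12, 24, 36, 60, 84, 96,
108, 120 months) with Gaussian jitter (SD 0.8 months) and independent 15%
missingness per (visit, measure); the preoperative visit is never missing.
Covariate prevalences default to published control-column proportions
(e.g., diabetes ≈ 0.11, heart disease ≈ 0.12, cuff-tear arthropathy 0.38
for rTSA vs. 0.007 for aTSA). Patient-reported scores (VAS pain, global
function, ASES, Constant, SAS) are generated with a plain saturating
approach and carried as opaque columns — they exist for reporting only.

**What the generator does not emulate**: real visit-level correlation
structure beyond the shared latent class, informative missingness or loss to
follow-up, surgeon/site effects, measurement floor effects near 0°, and any
dependence of the dip between the <60° and ≥120° extremes other than the
linear-above-threshold form. Passing tests therefore demonstrate that the
pipeline's statistics behave correctly on data with the assumed structure,
not that the structure exhausts real clinical data.

## Numerical choices

* Voting thresholds compared as `fractions.Fraction` — no floating-point
  ambiguity at exactly 2/3 or 1/3.
* Strict exceedance (rate > mean): a rate exactly at the cohort mean has not
  "exceeded" it.
* Half-up rounding everywhere a published-style figure is produced
  (9.5° → 10°; 0.9 IR points → 1.0 on the half-point grid); Python's
  banker's rounding is never used for reported values.
* Degenerate t-test inputs (both samples constant and equal) return
  (t = 0, p = 1) rather than NaN, so constant factors are cleanly
  non-significant and excluded from the multivariate step.
* Fisher's test with a zero margin gives p = 1; no continuity corrections.
* IRLS covariance uses a floor of 1e-12 on the weights to keep the
  information matrix invertible in near-separated fits.
* CSV artifacts are written with a fixed `%.10g` float format and the run
  log carries no wall-clock content, so identical config + seed reproduces
  outputs byte for byte (stage timings go to the console logger only).

## Problem sizes

Default test and acceptance problem sizes were chosen to make Monte-Carlo
checks stable at desk scale: 200–600 patients per simulated cohort, 50
replicates for planted-effect recovery, 100 permutations for null
calibration, 500 random tables for the Fisher oracle, and the exhaustive
(n ≤ 40) voting grid. The full published cohort (688 + 584 patients, 8357
visits) is an order of magnitude larger than needed for these properties.

## Known limitations

* The voting rule's vote unit ("their ROI measures") is ambiguous between
  per-visit rates and per-measure averages; both are implemented, per-visit
  is the default.
* The decline denominator (since peak vs. since surgery) cannot be
  disambiguated from published cohort tables; both are implemented,
  time-since-peak is the default.
* Univariate-then-multivariate screening inherits the usual caveats
  (selection on significance, collinearity among preop ROM measures); the
  screen reports exactly the univariate-significant set and drops constant
  columns, but performs no further variable selection or diagnostics.
* Fisher's exact test is conservative for small cells; its realized type-I
  error under permutation nulls sits below the nominal 5%.
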