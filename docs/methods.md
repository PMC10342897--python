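# Methods

## Classification model

Blood-pressure categories are resolved per visit from a `ThresholdSet`
(elevated and hypertension cutoffs for SBP and DBP) and then aggregated to
person-years of age.  The resolution rules:

- **2004 Fourth Report, ages 1–17.** Prehypertension begins at the lower of
  the 90th-percentile value and the 120/80 mmHg static floor (the floor
  applies even when the 90th percentile lies above it); hypertension begins
  at the 95th-percentile value **+ 5 mmHg**.  This +5 offset is implemented
  exactly as stated by the surveillance definition this package
  operationalizes; it differs from the original Fourth Report's stage
  boundaries, which this package deliberately does not model (no stage 1/2
  distinction anywhere).
- **AAP 2017, ages 1–12.** Elevated = min(90th percentile, 120/80);
  hypertension = min(95th percentile, 130/80).
- **AAP 2017, ages 13–17.** Static band, independent of sex and height:
  elevated 120/80, hypertension 130/80.
- **Both guidelines, ages 18–20.** Adult rule: hypertension 140/90 (the
  diastolic cutoff is taken as 90, the more standard adult definition,
  where source material is internally inconsistent about 89 vs 90);
  elevated keeps the 120/80 floor.

The elevated band's "and/or" logic is implemented as: a reading is elevated
iff (SBP ≥ elevated_sbp or DBP ≥ elevated_dbp) and it is not hypertensive.
This reproduces the printed band boundaries without ambiguity.

**Person-year aggregation.** SBP and DBP occasion counts are tracked
separately and OR-ed: hypertension requires ≥3 distinct-date occasions at or
above the systolic cutoff, or ≥3 at or above the diastolic cutoff.  A mixed
pattern (2 high-SBP + 2 high-DBP occasions) does not qualify — the literal
reading of "≥3 SBP and/or ≥3 DBP".  Elevated person-years use the identical
logic; hypertension takes precedence.  Readings at hypertension level also
count toward the elevated tally (the cutoffs are nested).  Same-date repeat
readings collapse to one occasion (first of day by default; per-day mean is
available).  Person-years with 1–2 occasions are *ineligible*: they are
reported with category NORMAL and `eligible=False`, can never be cases, and
by default (`denominator="any_obp"`) remain in rate and agreement
denominators; `eligible_only` restricts to ≥3-occasion person-years.  Age is
integer years attained: the age-k window is [k-th birthday, (k+1)-th
birthday).

## Quality control

Filter order is fixed: complete BP → height present → growth outliers →
BP outliers → minimum occasions.  The three record-level filters commute
(total survivors are order-invariant; tested on random cohorts), so the
order matters only for how exclusions are attributed in the attrition
report.  All exclusion inequalities are strict as printed: growth z-scores
of exactly ±6 and BP readings of exactly 240/60/160/30 mmHg are retained
(a relative tolerance of 1e-9 on the z-boundary absorbs float round-trip
noise).  "Three separate measurements at least 1 day apart" is read as ≥3
distinct calendar dates; for larger gap requirements the maximal qualifying
subset is found greedily over sorted dates.  Height exclusion is per-visit
by default (a person disappears only when no visit survives); a
person-level mode is available because the participant-level phrasing of
the source definition is ambiguous.

## Growth references and interpolation

Growth references use the LMS (Box–Cox) parameterization; z-scores use the
standard transform with the log-normal limit at L = 0 (continuous, and
guarded numerically below |L| < 1e-12).  L, M and S are each interpolated
linearly between bracketing month rows — simple and monotone on smooth
references.  BP reference values are interpolated linearly across the
height-percentile grid columns {5, 10, 25, 50, 75, 90, 95}; height
percentiles outside [5, 95] clamp to the boundary column, matching common
clinical-calculator practice.  The loaders enforce schema and monotonicity
invariants (M, S > 0; strictly increasing ages; values strictly increasing
in BP percentile and non-decreasing in height percentile) and report the
offending row.

## Statistics

- **Rates.** Cases per 1000 person-year units at risk, rounded half-up to
  2 decimals (presentation convention).  Age groups {1–7, 8–12, 13–17,
  18–20} are not mutually exclusive; a person contributes one unit per
  age-year inside a group.  Annual rates use distinct persons with ≥1 OBP
  visit in the calendar year as the denominator and persons with a
  hypertensive person-year overlapping that year (any of its visits in the
  year) as the numerator.
- **Agreement.** Hypertension vs not, per person-year unit, across the two
  guidelines.  Cohen's κ = (p_o − p_e)/(1 − p_e); the standard error uses
  the Fleiss–Cohen–Everitt large-sample variance (no formula is mandated by
  the surveillance definition; this choice is cross-checked against a
  10,000-replicate multinomial bootstrap in the test suite, agreeing within
  15%).  CI = κ ± 1.96·SE truncated to [−1, 1].  Interpretation bands:
  ≤0.20 none, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
  0.81–1.00 almost perfect, applied after rounding κ to 2 decimals.
  Degenerate margins (p_e = 1) raise a kappa-undefined error that still
  carries percent agreement.
- **Associations.** The source analysis names a "conditional" logistic
  regression without stating its matching structure; this package fits an
  ordinary maximum-likelihood logistic model stratified by age group
  (statsmodels, Newton, 100 iterations, tolerance 1e-8) and reports
  exp(coefficient) with Wald 95% CIs.  Complete separation is detected per
  covariate and reported by name; a singular design raises.  The outcome
  contrast is hypertension vs elevated + normal pooled.
- **BMI.** kg/m², categorized by LMS percentile: underweight <5th,
  overweight [85th, 95th), obesity ≥95th.

## PMCA

Medical complexity follows the conservative variant of the Pediatric
Medical Complexity Algorithm: a condition qualifies on ≥2 distinct
outpatient/ED encounter dates with a mapped code (two codes on one date do
not qualify — a guard against same-visit duplicate coding) or ≥1
inpatient-discharge code, inside the half-open window [index − 365 d,
index).  Complex chronic disease = ≥2 body systems or any progressive
condition or malignancy; exactly one unflagged system is non-complex; an
empty set is without chronic disease.  The published PMCA v2.0 code lists
are not bundled; the module is driven by a user-supplied prefix map
(longest-prefix matching, unmapped codes tallied but ignored), and a
synthetic 18-system map ships for tests.  The index date defaults to the
first OBP visit (of the study, or of each age-year, per caller).

## Synthetic data

The generator emulates the *structure* of a pediatric outpatient EHR, not
any population's calibration.  Defaults are fixed study conditions: 2000
persons, window 2009–2018, ages 1–20, mean 2.8 visits per observed
person-year and ~2.7 observed age-years per person (matching the visit- and
person-year densities typical of such panels), hypertension planted at 5
and elevated BP at 3 per 1000 person-years, defect rates of 5% missing
heights, 0.2% BP outliers and 0.1% growth outliers per visit.  All rows of
the synthetic growth reference use L = 1 so closed-form test cases exist.
Both guidelines' tables come from one Gaussian normative model (SBP:
85 + 2.4·age + 2.5·z_height ± sex shift, σ = 16; DBP: 45 + 1.9·age +
1.2·z_height, σ = 12), so inter-guideline differences arise purely from the
rules; the model's coefficients guarantee that at ages 13–17 the AAP static
130/80 sits at or below the 2004 rule's 95th + 5 everywhere on the grid
("aap_dominant"), reproducing the direction of reclassification seen in
practice.

Planted categories are realized against the *joint* threshold band of both
guidelines, so the truth label holds under each: hypertensive person-years
emit all-occasion readings above both hypertension cutoffs (70% via SBP,
30% via DBP), elevated person-years sit strictly inside the joint elevated
band (SBP only — diastolic elevated bands can be degenerate where the
80 mmHg cap binds), normals stay below both elevated cutoffs.  Readings
keep a ±2 mmHg margin from every boundary (configurable; where the joint
band narrows below twice the margin — possible where the 120 mmHg floor
crosses the percentile curves — the clearance adapts to a third of the band
width, which is provably positive on a valid table).  Cases are forced to
≥3 visits so the planted label is attainable; ground truth is recorded
before defect injection and person-years touched by a defect are flagged.
Visit dates are distinct uniform days within each age-year; an age-year
that begins late in the final study year may spill visits into the
following calendar year.

What passing tests therefore show: the pipeline's rule logic, accounting
and estimators are correct on data whose generating process is known.  What
they do not show: robustness to real-EHR phenomena the generator omits —
measurement rounding/terminal-digit preference, within-person BP
autocorrelation, informative visit frequency, guideline-discordant
boundary readings, coding drift between ICD-9 and ICD-10 eras.  The
generator plants BP independently of comorbidity and BMI, so association
analyses on synthetic data are null-calibration checks, not effect
demonstrations.

## Problem sizes

The test suite and acceptance script use cohorts of 2000 persons
(~5000 person-years, ~15,000 visits) and three seeds per planted prevalence
{0.001, 0.005, 0.05} — sizes at which a planted rate is recoverable within
3 binomial standard errors while the whole suite stays around a minute.

## Known limitations

- Printed κ values from the motivating surveillance analysis are not
  reproducible from its published marginals alone (the 2×2 denominators are
  underdetermined); both candidate denominators are supported via
  configuration, and no attempt is made to match those values.
- No stage 1 / stage 2 hypertension split, no ambulatory/home BP protocols,
  no infant (<1 y) references, no ICD-code-based case definitions.
- The logistic model is unconditional; with strong stratum effects and
  sparse cells it can differ from a matched conditional fit.
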