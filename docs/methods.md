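# Methods

This note documents the models and numerical choices behind pedigrowth:
what is computed, under which assumptions, and what the synthetic-data
tests do and do not demonstrate about real data.

## The LMS model

A growth reference described by the lambda-mu-sigma (LMS) method supplies,
for each age (and optionally sex), three parameters: L, the Box-Cox power
that normalises the skewness of the measurement distribution; M, the
median; and S, the coefficient of variation. A measurement x at that age
maps to a Z-score by

    z = ((x/M)^L − 1) / (L·S)   if L ≠ 0
    z = ln(x/M) / S             if L = 0

and the inverse (the measurement at a given Z) is

    x = M·(1 + L·S·z)^(1/L)     if L ≠ 0
    x = M·exp(S·z)              if L = 0.

The model assumes the Box-Cox-transformed measurement is normal at every
age; percentiles are then the standard normal CDF of z.

Numerical choices:

- **L ≈ 0 branch.** |L| < 1e-12 is routed to the log branch. The power
  branch's numerator ((x/M)^L − 1) and denominator both vanish as L → 0
  and their ratio converges to the log form; switching branches below
  1e-12 avoids catastrophic cancellation while changing the result by far
  less than any measurement precision (continuity is tested at L = 1e-8
  against L = 0, agreement < 1e-6).
- **Representable range.** For L ≠ 0 the inverse transform requires
  1 + L·S·z > 0. Scalar calls outside it raise; vectorised calls yield
  NaN, and vectorised calls generally propagate missing/invalid elements
  as NaN instead of raising so cohort pipelines survive partial records.
- **Normal CDF.** Percentiles use the classical rational approximation to
  Φ (Abramowitz & Stegun eq. 26.2.17: five-term polynomial in
  t = 1/(1 + 0.2316419·|z|) times the normal density, reflected for
  z < 0). Its absolute error is below 7.5e-8, verified in the tests
  against scipy's high-precision `ndtr` over z ∈ [−8, 8]. The inverse
  (percentile → z) is solved by Brent bracketed root search on that same
  approximation over z ∈ [−13, 13], so the pair is self-consistent to
  ~1e-6 in percentile points.

## Charts: interpolation and age centering

A chart is a table of (sex, age, L, M, S) knots plus conventions.
Intermediate ages get component-wise **linear** interpolation of L, M and
S between the bracketing knots; exact knot ages return the stored values
bit-exactly. No extrapolation: any age outside the knot range raises a
range error, because published references bound their age ranges without
defining behaviour beyond them. Ages below the first knot (e.g. between
birth and the first monthly knot of an infant chart) are likewise a range
error, not a guess.

Published tables label rows by completed age interval, not interval
centre. The `centering_offset` records what must be added to a label to
get the exact age it represents, and lookups subtract it:

| convention | offset | meaning |
|---|---|---|
| weekly preterm chart, midweek centred (Fenton-2003 style) | 3/7 wk | label *w* ≡ exact age *w* 3/7 |
| monthly infant chart, half-month centred (CDC style) | 0.5 mo | label *m* ≡ exact age *m*.5 |
| daily-resolution chart | 0 | interpolation effectively unnecessary |

The package ships these conventions as named presets (fenton2003,
fenton2013, cdc_infant, cdc_pediatric, who_infant, olsen2010) but **no
third-party LMS parameter values**: CDC/WHO/Olsen tables are loaded from
user-supplied files in either the canonical `sex,age,L,M,S` CSV dialect
or the published CDC data-file dialect (numeric sex codes, `Agemos`
column), and the Fenton 2013 parameters are licensed and must likewise be
supplied by the user. Synthetic charts (below) cover all testing.
Unit conversions use 7 days/week exactly and 30.4375 days/month (the mean
calendar month); serialising a chart writes shortest-round-trip floats so
load → save → load is bit-identical.

Sex handling: sex-specific charts require male or female; non-sex-specific
charts ignore a supplied sex with a logged notice (mirroring preterm
references that are not sex-specific).

## Age arithmetic

All date arithmetic is calendar-day counting. The anchor is the
obstetric 280-day LMP-to-due-date convention: GA on date d is
280 − (due − d) days. Any sufficient anchor set (LMP; due date; birth
date + GA at birth) may be given; redundant anchors that disagree raise a
consistency error rather than silently preferring one, since silent
preference hides data-entry faults. Corrected age subtracts the shortfall
from 40 0/7 weeks and is returned negative (flagged) before
term-equivalent age.

## Single-visit and longitudinal assessment

Per observation: z, percentile, the expected median (the measurement at
z = 0), and the **maintenance gain** — the change over exactly the next 7
days that holds the current Z. If age + 7 days leaves the chart the gain
is reported unavailable instead of shortening the horizon, which would
silently change its units. Unit conversion uses the exact definitions
1 lb = 453.59237 g (16 oz/lb) and 1 in = 2.54 cm. Pediatric extreme
obesity is BMI ≥ 120% of the age/sex 95th-percentile BMI or ≥ 35 kg/m²,
both inclusive.

For a series, each pair of consecutive weight measurements yields the
observed gain (g/week), the expected gain to hold the previous visit's
percentile, and the Z velocity dz_rate = Δz / Δweeks with elapsed weeks as
a real number. The traffic-light rule (weight only, applied when day of
life > 10 at the later visit):

- red: dz_rate < −0.06 SD/week
- yellow: −0.06 ≤ dz_rate < −0.03
- green: otherwise (exactly −0.03 is green, exactly −0.06 yellow — the
  rule is "decrease by *more than*").

Sustained at the thresholds over a 14-week admission these rates
accumulate ∆Z = −0.84 and −0.42 respectively; the per-visit rates
telescope exactly to z_last − z_first. Each visit is compared with the
immediately preceding visit that had an assessable weight (not a fixed
baseline). Deidentified series may carry per-visit postmenstrual ages
instead of dates, so no dates need leave a site.

## Cohort analysis

Records come from VON-style (eNICQ) exports — CSV, XML or JSON with the
registry column names (GAWEEKS, GADAYS, BWGT, LOS1, DWGT, FDISP, CMAL,
LOCATE, DAYADMISS, BYEAR). Code mappings (FDISP 1/2/3 →
home/transfer/death, LOCATE 1 → inborn, nonzero CMAL → malformation) are
package conventions documented here. Malformed rows are flagged and
counted, never silently dropped.

Derived quantities: GA = GAWEEKS + GADAYS/7; discharge PMA = GA at birth
+ LOS1 days (LOS counted from birth); z at birth and discharge from the
chosen preterm weight reference; ∆Z = z_discharge − z_birth, the growth
outcome metric (more negative = greater faltering relative to the
reference).

Eligibility: GA 23 0/7–34 6/7; survival to discharge; no severe
malformation; BWGT, DWGT, LOS present; both |Z| ≤ 4 (strictly beyond ±4
usually indicates data-entry error; exactly ±4 retained). Records whose
discharge PMA exits the chart are excluded with their own tally
(`chart_range`), never extrapolated. Exclusions are attributed to the
*first* failing criterion in a fixed order (ga_range, death, disposition,
malformation, missing_fields, z_range, chart_range) so tallies are stable
and sum with the eligible count to the input count. Optional stricter
disposition filters (exclude transfers / require home discharge) exist
because registries differ in transfer practice; both default off.

The model is ordinary least squares of ∆Z on (GA − 29 weeks) with a full
per-group (hospital or epoch) interaction: one indicator and one
indicator-by-centred-GA column per group, i.e. a separate line per group
estimated jointly with a shared residual variance and classical
homoskedastic standard errors. Centering at 29 0/7 weeks makes each
group's intercept exactly its expected ∆Z at 29 weeks; changing the
center shifts intercepts by slope·Δcenter and leaves slopes unchanged
(tested). A designated reference group re-parameterises the same fit to
expose difference-from-reference contrasts. Groups need ≥ 2 records and
≥ 2 distinct GAs or the fit refuses with the group named. Pairwise
comparison of group mean ∆Z uses Tukey's HSD; it never touches the
regression table.

## Synthetic data: what it emulates and what it does not

`make_chart` builds charts from parametric curves (linear or logistic M,
constant or linear S, constant L). The default preterm-weight shape —
weekly knots over 22–50 postmenstrual weeks, logistic M from ~430 g at
23 weeks through ~1100 g at 29.5 to a ~3300 g region at term, S = 0.13,
L = 1 — mimics the *shape* of published preterm references, not their
values. L = 1 with constant S gives the closed form z = (x − M)/(M·S),
used as the hand-checkable oracle throughout the tests.

`simulate_cohort` draws GA uniformly over 23 0/7–34 6/7 (whole days),
birth Z from a normal (default mean −0.19, SD 0.84, the level a large
multicentre preterm registry shows) truncated to ±4 by resampling, and
∆Z = intercept_g + slope_g·(GA − 29) + N(0, noise_sd) with the discharge
Z also kept within ±4 by resampling, so planted group sizes survive the
pipeline's exclusion rule untouched. Discharge timing targets a normal
PMA (default 37 ± 1.8 weeks) clipped into the chart domain with a minimum
one-week stay. Weights are realised through the chart's own quantile
transform, so recomputing Z from the emitted weights recovers the planted
Z exactly; with noise_sd = 0 the model fit recovers planted parameters to
~1e-10. The default seven-hospital effect set plants intercepts from
−0.55 to −1.05 (hospital F at −0.553 with slope −0.001, the others with
slopes +0.02 to +0.045) and group sizes summing to 7975 — the magnitude
and spread of hospital-level ∆Z variation reported by multicentre NICU
growth studies. Default residual SD is 0.45, consistent with reported
per-hospital ∆Z SDs of ~0.4–0.6 after removing the GA trend.

What the synthetic cohorts do **not** emulate: the right-skewed GA
distribution of real NICU admissions (uniform GA is used, so pooled means
weight gestations differently than a real registry), GA-dependent length
of stay, morbidity covariates, year effects, missingness patterns, or
intra-hospital correlation. Passing recovery and coverage tests therefore
demonstrates correctness of the estimator and pipeline under the stated
generative model — not that real interhospital differences of a given
size would be detected at a given power.

## Problem sizes and runtime defaults

The default test and acceptance runs use: the full default synthetic
cohort (7975 records) once; two-group recovery designs at n = 500/group;
and 200 seeded replicates for the 95% CI coverage estimate (expected
coverage within [0.90, 0.99]). These sizes give Monte-Carlo error small
enough for 3-SE recovery checks and ~±1.5% coverage resolution while
keeping a full run in the low minutes on one CPU.

## Known limitations

- Only LMS-parameterised references are supported (no 4-parameter
  GAMLSS/skew-t or quantile-regression charts).
- No extrapolation policy beyond chart knots, by design; callers must
  handle the range error or accept the cohort `chart_range` exclusion.
- Classical OLS standard errors only; no clustering by hospital or robust
  variants.
- The gestational-age calculator implements the 280-day convention only;
  ultrasound re-dating rules are out of scope.
- Display rounding is a CLI concern; library functions never round.
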