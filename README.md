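# pedigrowth

Growth-chart computation and growth-outcome analysis for pediatric and
preterm populations, built on the lambda-mu-sigma (LMS) parameterisation
of growth references.

Paper growth charts only show a handful of centile lines; an LMS table —
the Box-Cox skewness power L, median M and coefficient of variation S at
each age — lets you compute an *exact* Z-score and percentile for any
measurement, invert any centile back to a measurement, and track growth
quantitatively over time. pedigrowth implements that math and everything
clinicians and clinical researchers build on top of it:

- **LMS engine** — `x_to_z`, `z_to_x` (Box-Cox transforms,
  z = ((x/M)^L − 1)/(L·S), with the log form at L = 0), percentile
  conversion via the Abramowitz–Stegun rational normal-CDF approximation
  and its bracketed-root inverse.
- **Chart registry** — load/validate LMS tables (canonical
  `sex,age,L,M,S` CSV or the published CDC data-file dialect), linear
  interpolation between knots, and the age-centering conventions of real
  references (midweek-centred weekly preterm labels, half-month-centred
  monthly infant labels). No extrapolation, ever.
- **Age tools** — gestational/postmenstrual age from any sufficient
  combination of LMP, due date, birth date, GA at birth and chronologic
  age (280-day convention; conflicting inputs are an error), plus
  corrected age for prematurity.
- **Patient calculator** — Z, percentile, expected median for age, the
  weekly gain needed to hold the current percentile, metric/imperial
  units (453.59237 g/lb, 2.54 cm/in), BMI, and extreme-obesity
  categorisation (BMI ≥ 120% of the 95th percentile or ≥ 35 kg/m²).
- **Longitudinal decision support** — per-visit Z trajectory, observed
  vs expected weekly weight change, and the ∆Z/week traffic light: red
  for a fall of more than 0.06 SD/week, yellow more than 0.03, green
  otherwise, applied after the first 10 days of life.
- **Cohort analysis** — import VON-style registry exports (CSV/XML/JSON),
  apply NICU eligibility rules (GA 23 0/7–34 6/7, survival, no
  malformation, |Z| ≤ 4), compute each infant's birth-to-discharge change
  in weight Z-score (∆Z), and fit ∆Z ~ gestational age with per-hospital
  (or per-epoch) intercept and slope interactions centred at 29 weeks.
- **Synthetic data** — parametric LMS charts, scripted-Z patient
  trajectories, and VON-shaped cohorts with planted hospital effects,
  fully seed-deterministic, for testing and method validation. No
  third-party LMS tables are bundled (several are licensed); real charts
  load from user-supplied files.

## Worked example

A 1300 g infant at 30 weeks postmenstrual age on the built-in synthetic
preterm weight chart:

```text
$ growth assess --age 30 --value 1300
value_metric      1300
value_imperial    2 lb 13.9 oz
z                 0.7257
percentile        76.60
expected_median   1187.93
maintenance_gain  192.703 per week
```

The infant is 0.73 SD above the reference median (77th percentile); the
median weight for this age is 1188 g, and gaining ~193 g over the next
week would exactly hold the 77th percentile.

```text
$ growth ga --birth-date 2020-03-10 --ga-weeks 28 --chronologic-days 17
gestational_age  30 3/7 (213 days)
chronologic_age  17 days
corrected_age    -67 days (before term-equivalent age)
```

The same from Python, including a cohort round trip:

```python
import pedigrowth as pg

chart = pg.make_chart()                      # synthetic preterm weight chart
lms = pg.lms_at(chart, None, 30.0)           # interpolated (L, M, S) at 30 wk
z = pg.x_to_z(1300.0, lms)                   # 0.7257...

df = pg.simulate_cohort(seed=1)              # VON-dialect, 7 hospitals, n=7975
records, _ = pg.recode_von(df)
eligible, report = pg.apply_eligibility(records, chart)
fit = pg.fit_delta_z_model(eligible, reference="F")
print(fit.groups[["n", "intercept", "slope"]])
```

which prints each hospital's expected ∆Z at 29 0/7 weeks (intercept) and
its change per week of gestational age (slope), with hospital F's
difference contrasts available in `fit.contrasts`.

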