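"""Longitudinal assessment of one patient's measurement series.

For each visit: per-measure Z-scores and percentiles; the observed weekly
weight change since the previous visit; the expected weekly change needed
to hold the previous visit's percentile; and the weight Z-score velocity
``dz_rate = (z_now - z_prev) / elapsed weeks`` with a traffic-light flag.

The flag rule (applied to weight only, after the first 10 days of life):
red when the Z-score falls by *more than* 0.06 SD/week, yellow by more
than 0.03 SD/week, green otherwise.  Sustained at exactly the red
threshold over a 14-week admission, the loss telescopes to delta-Z = -0.84
SD; at the yellow threshold, -0.42 SD.

Series may carry real visit dates together with a birth date, or — for
deidentified use, where no dates can leave the site — a postmenstrual age
per visit plus the gestational age at birth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from io import StringIO

import pandas as pd

from .ages import GestationalAge, _to_date
from .charts import ChartSpec
from .errors import GrowthError, UsageError
from .lms import z_to_x
from .patient import GrowthAssessment, Observation, assess

__all__ = [
    "Visit",
    "VisitSeries",
    "VisitAssessment",
    "flag_dz_rate",
    "assess_series",
    "read_visits_csv",
    "series_report",
]

#: day-of-life after which the delta-Z colour rule applies
FLAG_MIN_DAY_OF_LIFE = 10
#: SD/week thresholds; "decrease by more than" => strict inequalities
RED_RATE = -0.06
YELLOW_RATE = -0.03

_MEASURE_FIELDS = {
    "weight": "weight_g",
    "length": "length_cm",
    "head_circumference": "head_circumference_cm",
}


@dataclass(frozen=True)
class Visit:
    """One visit: a date or a postmenstrual age, plus any measurements."""

    when: date | None = None
    pma: GestationalAge | None = None
    weight_g: float | None = None
    length_cm: float | None = None
    head_circumference_cm: float | None = None

    def __post_init__(self):
        if self.when is None and self.pma is None:
            raise UsageError("each visit needs a date or a postmenstrual age")
        if all(
            getattr(self, f) is None for f in _MEASURE_FIELDS.values()
        ):
            raise UsageError("each visit needs at least one measurement")


@dataclass
class VisitSeries:
    """An ordered measurement series for one patient."""

    sex: str
    ga_at_birth: GestationalAge
    visits: list[Visit]
    birth_date: date | None = None

    def __post_init__(self):
        if not self.visits:
            raise UsageError("series has no visits")
        pma = [self.pma_days(v) for v in self.visits]
        if any(b <= a for a, b in zip(pma, pma[1:])):
            raise UsageError("visits must be strictly increasing in time")

    def pma_days(self, visit: Visit) -> int:
        """Postmenstrual age of a visit in days."""
        if visit.when is not None:
            if self.birth_date is None:
                raise UsageError(
                    "visits carry dates but the series has no birth_date"
                )
            return self.ga_at_birth.total_days + (visit.when - self.birth_date).days
        return visit.pma.total_days

    def day_of_life(self, visit: Visit) -> int:
        return self.pma_days(visit) - self.ga_at_birth.total_days


@dataclass
class VisitAssessment:
    """Derived quantities for one visit within a series.

    Rate quantities (``observed_gain``, ``expected_gain`` in g/week and
    ``dz_rate`` in SD/week) refer to the immediately preceding visit that
    had an assessable weight; they are None — and the flag
    ``not_applicable`` — at the first visit, when the previous weight is
    missing, or within the first 10 days of life.
    """

    pma: GestationalAge
    day_of_life: int
    assessments: dict[str, GrowthAssessment] = field(default_factory=dict)
    observed_gain: float | None = None
    expected_gain: float | None = None
    dz_rate: float | None = None
    flag: str = "not_applicable"
    error: str | None = None


def flag_dz_rate(dz_rate: float, day_of_life_at_visit: int) -> str:
    """Traffic-light flag for a weight Z-score velocity (SD/week).

    ``not_applicable`` through day of life 10; red for a fall of more than
    0.06 SD/week; yellow for more than 0.03; green otherwise.  Exactly
    -0.06 is yellow and exactly -0.03 is green (the rule is "more than").
    """
    if day_of_life_at_visit <= FLAG_MIN_DAY_OF_LIFE:
        return "not_applicable"
    if dz_rate < RED_RATE:
        return "red"
    if dz_rate < YELLOW_RATE:
        return "yellow"
    return "green"


def _charts_by_measure(charts) -> dict[str, ChartSpec]:
    if isinstance(charts, ChartSpec):
        return {charts.measure: charts}
    return dict(charts)


def assess_series(series: VisitSeries, charts) -> list[VisitAssessment]:
    """Assess every visit of a series against one or more growth references.

    ``charts`` is a single :class:`ChartSpec` or a mapping from measure
    name to chart.  A visit whose postmenstrual age falls outside a chart's
    domain is flagged with an error message but does not stop the
    remaining visits from being assessed; rate quantities then skip over
    it to the last visit with a valid weight Z.
    """
    chart_map = _charts_by_measure(charts)
    out: list[VisitAssessment] = []
    prev_weight: tuple[int, float, float] | None = None  # (pma_days, weight, z)
    for visit in series.visits:
        pma_days = series.pma_days(visit)
        va = VisitAssessment(
            pma=GestationalAge.from_days(pma_days),
            day_of_life=series.day_of_life(visit),
        )
        errors = []
        for measure, fieldname in _MEASURE_FIELDS.items():
            value = getattr(visit, fieldname)
            chart = chart_map.get(measure)
            if value is None or chart is None:
                continue
            age_native = pma_days / _native_days(chart)
            try:
                obs = Observation(measure=measure, value=value,
                                  age=age_native, sex=series.sex)
                va.assessments[measure] = assess(obs, chart)
            except GrowthError as exc:
                errors.append(f"{measure}: {exc}")
        if errors:
            va.error = "; ".join(errors)

        weight_chart = chart_map.get("weight")
        wa = va.assessments.get("weight")
        if wa is not None and weight_chart is not None:
            if prev_weight is not None:
                prev_days, prev_w, prev_z = prev_weight
                weeks = (pma_days - prev_days) / 7.0
                va.observed_gain = (visit.weight_g - prev_w) / weeks
                hold = z_to_x(
                    prev_z,
                    _lms_native(weight_chart, series.sex, pma_days),
                )
                va.expected_gain = (hold - prev_w) / weeks
                va.dz_rate = (wa.z - prev_z) / weeks
                va.flag = flag_dz_rate(va.dz_rate, va.day_of_life)
            prev_weight = (pma_days, visit.weight_g, wa.z)
        out.append(va)
    return out


def _native_days(chart: ChartSpec) -> float:
    from .charts import DAYS_PER_UNIT

    return DAYS_PER_UNIT[chart.age_unit]


def _lms_native(chart: ChartSpec, sex, pma_days: int):
    from .charts import lms_at

    return lms_at(chart, sex, pma_days / _native_days(chart))


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_visits_csv(source) -> VisitSeries:
    """Read a one-visit-per-row CSV into a :class:`VisitSeries`.

    Expected header: ``sex, ga_weeks, ga_days`` plus either ``date`` or
    ``pma_weeks, pma_days``, and any of ``weight_g, length_cm, hc_cm``.
    Sex and gestational age are taken from the first row.
    """
    if isinstance(source, str) and "\n" in source:
        source = StringIO(source)
    if hasattr(source, "read"):
        rows = list(csv.DictReader(source))
    else:
        with open(source, newline="") as fh:
            rows = list(csv.DictReader(fh))
    if not rows:
        raise UsageError("visit file is empty")

    def _num(row, key):
        v = (row.get(key) or "").strip()
        return float(v) if v else None

    first = rows[0]
    if "ga_weeks" not in first:
        raise UsageError("visit file must carry ga_weeks (and ga_days) columns")
    ga = GestationalAge(int(float(first["ga_weeks"])),
                        int(float(first.get("ga_days") or 0)))
    sex = (first.get("sex") or "unspecified").strip() or "unspecified"
    birth_date = None
    visits = []
    for row in rows:
        when = None
        pma = None
        if (row.get("date") or "").strip():
            when = _to_date(row["date"].strip(), "date")
        elif (row.get("pma_weeks") or "").strip():
            pma = GestationalAge(int(float(row["pma_weeks"])),
                                 int(float(row.get("pma_days") or 0)))
        visits.append(
            Visit(
                when=when,
                pma=pma,
                weight_g=_num(row, "weight_g"),
                length_cm=_num(row, "length_cm"),
                head_circumference_cm=_num(row, "hc_cm"),
            )
        )
    if any(v.when is not None for v in visits):
        if not (first.get("birth_date") or "").strip():
            raise UsageError(
                "dated visit files must carry a birth_date column"
            )
        birth_date = _to_date(first["birth_date"].strip(), "birth_date")
    return VisitSeries(sex=sex, ga_at_birth=ga, visits=visits,
                       birth_date=birth_date)


def series_report(assessments: list[VisitAssessment]) -> pd.DataFrame:
    """Tabulate per-visit results (one row per visit) for display or CSV."""
    rows = []
    for va in assessments:
        row = {
            "pma": str(va.pma),
            "day_of_life": va.day_of_life,
            "observed_gain_per_week": va.observed_gain,
            "expected_gain_per_week": va.expected_gain,
            "dz_rate_per_week": va.dz_rate,
            "flag": va.flag,
            "error": va.error,
        }
        for measure, ga in va.assessments.items():
            row[f"{measure}_z"] = ga.z
            row[f"{measure}_percentile"] = ga.percentile
            row[f"{measure}_expected_median"] = ga.expected_median
        rows.append(row)
    return pd.DataFrame(rows)
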