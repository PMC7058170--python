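"""Single-observation clinical calculator.

Given one anthropometric measurement and a growth reference, compute the
Z-score, percentile, the expected median for age, and the *maintenance
gain*: how much the measurement must increase over the next 7 days for the
patient to hold the current Z-score (equivalently, to keep growing along
the current percentile curve).  Also provides metric/imperial unit
conversion, BMI computation, and the extreme-obesity categorisation
(BMI >= 120% of the age/sex 95th percentile, or >= 35 kg/m^2).
"""

from __future__ import annotations

from dataclasses import dataclass

from .charts import DAYS_PER_UNIT, ChartSpec, lms_at
from .errors import ChartRangeError, DomainError, UsageError
from .lms import percentile_to_z, x_to_z, z_to_percentile, z_to_x

__all__ = [
    "Observation",
    "GrowthAssessment",
    "assess",
    "convert_units",
    "lb_oz_to_g",
    "g_to_lb_oz",
    "compute_bmi",
    "classify_obesity",
    "bmi_p95",
]

# exact definitional constants
G_PER_LB = 453.59237
OZ_PER_LB = 16
CM_PER_IN = 2.54

_TO_G = {"g": 1.0, "kg": 1000.0, "lb": G_PER_LB, "oz": G_PER_LB / OZ_PER_LB}
_TO_CM = {"cm": 1.0, "m": 100.0, "in": CM_PER_IN, "mm": 0.1}


@dataclass(frozen=True)
class Observation:
    """One measurement of one measure at one age.

    ``value`` is always stored metric (g for weight, cm for lengths and
    circumferences, kg/m^2 for BMI); ``age`` is in the chart's native unit
    (e.g. postmenstrual weeks for preterm charts, months for infant
    charts).  ``source_units`` records how the value was originally entered
    and is a display concern only.
    """

    measure: str
    value: float
    age: float
    sex: str = "unspecified"
    source_units: str = "metric"

    def __post_init__(self):
        if not self.value > 0:
            raise DomainError(f"measurement must be positive, got {self.value!r}")


@dataclass(frozen=True)
class GrowthAssessment:
    """Derived quantities for one observation.

    ``maintenance_gain`` is the expected change over the next 7 days that
    holds the current Z-score, in measure units per week; it is None when
    age + 7 days leaves the chart domain (shortening the horizon would
    silently change the units, so it is reported unavailable instead).
    """

    z: float
    percentile: float
    expected_median: float
    maintenance_gain: float | None


def assess(obs: Observation, chart: ChartSpec) -> GrowthAssessment:
    """Assess one observation against a growth reference.

    Raises the underlying :class:`ChartRangeError`/:class:`DomainError`
    when the age or value is outside the chart's representable range.
    """
    if obs.measure != chart.measure:
        raise UsageError(
            f"observation measure {obs.measure!r} does not match chart "
            f"measure {chart.measure!r}"
        )
    lms = lms_at(chart, obs.sex, obs.age)
    z = x_to_z(obs.value, lms)
    percentile = z_to_percentile(z)
    expected_median = z_to_x(0.0, lms)
    age_next = obs.age + 7.0 / DAYS_PER_UNIT[chart.age_unit]
    try:
        lms_next = lms_at(chart, obs.sex, age_next)
    except ChartRangeError:
        gain = None
    else:
        gain = z_to_x(z, lms_next) - obs.value
    return GrowthAssessment(z, percentile, expected_median, gain)


def convert_units(value: float, unit_in: str, unit_out: str) -> float:
    """Convert between mass units (g, kg, lb, oz) or length units
    (cm, m, in, mm) using the exact definitions 1 lb = 453.59237 g and
    1 in = 2.54 cm.  Incompatible unit pairs raise :class:`UsageError`."""
    ui, uo = unit_in.lower(), unit_out.lower()
    if ui in _TO_G and uo in _TO_G:
        return value * _TO_G[ui] / _TO_G[uo]
    if ui in _TO_CM and uo in _TO_CM:
        return value * _TO_CM[ui] / _TO_CM[uo]
    raise UsageError(f"incompatible or unknown unit pair {unit_in!r} -> {unit_out!r}")


def lb_oz_to_g(pounds: float, ounces: float = 0.0) -> float:
    """Pounds-and-ounces to grams (16 oz per lb)."""
    if pounds < 0 or ounces < 0:
        raise DomainError("pounds and ounces must be non-negative")
    return (pounds + ounces / OZ_PER_LB) * G_PER_LB


def g_to_lb_oz(grams: float) -> tuple[int, float]:
    """Grams to (whole pounds, remaining ounces)."""
    if grams < 0:
        raise DomainError("grams must be non-negative")
    total_lb = grams / G_PER_LB
    lb = int(total_lb)
    return lb, (total_lb - lb) * OZ_PER_LB


def compute_bmi(weight_kg: float, length_or_height_cm: float) -> float:
    """Body-mass index, kg/m^2."""
    if not (weight_kg > 0 and length_or_height_cm > 0):
        raise DomainError(
            f"weight and height must be positive, got {weight_kg!r}, "
            f"{length_or_height_cm!r}"
        )
    height_m = length_or_height_cm / 100.0
    return weight_kg / (height_m * height_m)


def bmi_p95(chart: ChartSpec, sex, age: float) -> float:
    """The BMI value at the 95th percentile for age and sex on a BMI chart."""
    return z_to_x(percentile_to_z(95.0), lms_at(chart, sex, age))


def classify_obesity(bmi: float, bmi_p95_value: float) -> str:
    """Categorise extreme obesity: ``"extreme"`` iff BMI >= 120% of the
    95th percentile BMI or BMI >= 35 kg/m^2, else ``"not_extreme"``.

    Both comparisons are inclusive (>=), matching the published definition.
    """
    if not (bmi > 0 and bmi_p95_value > 0):
        raise DomainError("bmi and bmi_p95 must be positive")
    if bmi >= 1.2 * bmi_p95_value or bmi >= 35.0:
        return "extreme"
    return "not_extreme"
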