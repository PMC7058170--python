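"""Synthetic data generators: smooth LMS chart tables, scripted single-
patient trajectories, and VON-shaped cohorts with planted per-hospital
delta-Z structure.

These generators are first-class package code, not test scaffolding: they
define the study conditions under which the cohort methodology is
exercised and validated.  All randomness flows from a single explicit seed
through one :class:`numpy.random.Generator`, so every artifact is
bit-reproducible.

Chart tables use simple parametric L/M/S curves (linear or logistic median,
constant or linear coefficient of variation, constant Box-Cox power).
With ``L = 1`` and constant ``S`` the Z transform reduces to the closed
form ``z = (x - M) / (M * S)``, which makes hand-checkable oracles easy.
The default preterm-weight shape spans 22-50 postmenstrual weeks with a
logistic median rising from a few hundred grams near the limit of
viability toward a plateau past term, mimicking the shape (not the values)
of published preterm references.

Cohorts are simulated from the same generative model the analysis fits:
``delta_z = intercept_g + slope_g * (ga_weeks - 29) + noise``, with
gestational age uniform over 23 0/7 to 34 6/7 weeks, a truncated-normal
birth Z, and weights realised through the chart's own quantile transform —
so the planted parameters are recoverable by construction and truncation
at |Z| = 4 mirrors the pipeline's exclusion rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ages import GestationalAge
from .charts import DAYS_PER_UNIT, ChartSpec
from .errors import DomainError, UsageError
from .lms import z_to_x
from .series import Visit, VisitSeries

__all__ = [
    "ChartShape",
    "GroupEffect",
    "CohortSimParams",
    "DEFAULT_HOSPITAL_EFFECTS",
    "make_chart",
    "simulate_trajectory",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ChartShape:
    """Parametric description of a synthetic LMS table.

    ``m_curve`` is ``("linear", a, b)`` for ``M = a + b * age`` or
    ``("logistic", lo, hi, midpoint, scale)`` for
    ``M = lo + (hi - lo) / (1 + exp(-(age - midpoint)/scale))``.
    ``s_curve`` is ``("constant", s)`` or ``("linear", a, b)``.
    ``sex_offset`` (same units as M) builds a sex-specific pair of tables
    with M shifted by +/- the offset; None builds a single
    non-sex-specific table.
    """

    name: str = "synthetic_preterm_weight"
    measure: str = "weight"
    age_unit: str = "gestational_weeks"
    age_min: float = 22.0
    age_max: float = 50.0
    step: float = 1.0
    m_curve: tuple = ("logistic", 100.0, 4800.0, 36.0, 5.0)
    s_curve: tuple = ("constant", 0.13)
    l_value: float = 1.0
    sex_offset: float | None = None
    centering_offset: float = 0.0

    def m_at(self, age: float) -> float:
        kind = self.m_curve[0]
        if kind == "linear":
            _, a, b = self.m_curve
            return a + b * age
        if kind == "logistic":
            _, lo, hi, mid, scale = self.m_curve
            return lo + (hi - lo) / (1.0 + math.exp(-(age - mid) / scale))
        raise UsageError(f"unknown M curve kind {kind!r}")

    def s_at(self, age: float) -> float:
        kind = self.s_curve[0]
        if kind == "constant":
            return self.s_curve[1]
        if kind == "linear":
            _, a, b = self.s_curve
            return a + b * age
        raise UsageError(f"unknown S curve kind {kind!r}")


def make_chart(shape: ChartShape = ChartShape()) -> ChartSpec:
    """Materialise a synthetic chart's knot table as a validated
    :class:`ChartSpec`.

    The knot values are exactly the shape's generating functions evaluated
    at the grid ages (deterministic; no noise is ever added to a chart).
    """
    if shape.step <= 0 or shape.step > (shape.age_max - shape.age_min):
        raise UsageError(
            f"step {shape.step} incompatible with domain "
            f"[{shape.age_min}, {shape.age_max}]"
        )
    n = int(round((shape.age_max - shape.age_min) / shape.step))
    ages = shape.age_min + shape.step * np.arange(n + 1)
    rows = []
    sexes = (
        [("male", +1.0), ("female", -1.0)]
        if shape.sex_offset is not None
        else [("unspecified", 0.0)]
    )
    for sex, sign in sexes:
        for a in ages:
            m = shape.m_at(float(a)) + sign * (shape.sex_offset or 0.0)
            if m <= 0:
                raise UsageError(
                    f"M curve non-positive at age {a}; adjust the shape"
                )
            rows.append(
                {"sex": sex, "age": float(a), "L": shape.l_value,
                 "M": m, "S": shape.s_at(float(a))}
            )
    return ChartSpec(
        name=shape.name,
        measure=shape.measure,
        age_unit=shape.age_unit,
        sex_specific=shape.sex_offset is not None,
        centering_offset=shape.centering_offset,
        records=pd.DataFrame(rows),
    )


def simulate_trajectory(
    chart: ChartSpec,
    z_schedule,
    *,
    ga_at_birth: GestationalAge,
    sex: str = "unspecified",
) -> VisitSeries:
    """Build a deidentified visit series following a scripted Z schedule.

    ``z_schedule`` is a sequence of ``(age, target_z)`` pairs with ages in
    the chart's native unit; each age is snapped to the nearest whole day
    of postmenstrual age (the resolution a deidentified series carries)
    and the weight is placed exactly at ``z_to_x(target_z, LMS at age)``.
    Running the result back through :func:`~pedigrowth.series.assess_series`
    therefore recovers the schedule's Z values to numerical precision
    whenever the schedule's ages are whole days.
    """
    from .charts import lms_at

    if not z_schedule:
        raise UsageError("z_schedule is empty")
    days_per_unit = DAYS_PER_UNIT[chart.age_unit]
    visits = []
    for age, z in z_schedule:
        pma_days = int(round(float(age) * days_per_unit))
        weight = z_to_x(float(z), lms_at(chart, sex, pma_days / days_per_unit))
        visits.append(
            Visit(pma=GestationalAge.from_days(pma_days), weight_g=weight)
        )
    return VisitSeries(sex=sex, ga_at_birth=ga_at_birth, visits=visits)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupEffect:
    """Planted delta-Z line for one group: the expected delta-Z at 29 0/7
    weeks (intercept) and its change per week of gestational age at birth
    (slope), with the group's size."""

    label: str
    intercept: float
    slope: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise UsageError(f"group {self.label!r} needs n >= 1")


#: Default seven-hospital structure.  Intercepts (expected delta-Z at
#: 29 0/7 weeks) span the -0.55 to -1.05 range that multicentre NICU
#: registry analyses report for birth-to-discharge weight delta-Z, and
#: slopes span 0 (a hospital whose growth outcome is flat in gestational
#: age) to ~+0.045 per week (strongly worse outcomes at lower gestational
#: ages).  Group sizes mirror the relative sizes of a realistic
#: seven-hospital sample totalling 7975 infants.
DEFAULT_HOSPITAL_EFFECTS: tuple[GroupEffect, ...] = (
    GroupEffect("A", -0.75, 0.035, 461),
    GroupEffect("B", -1.05, 0.030, 1586),
    GroupEffect("C", -0.80, 0.030, 1068),
    GroupEffect("D", -0.58, 0.020, 418),
    GroupEffect("E", -0.96, 0.045, 598),
    GroupEffect("F", -0.553, -0.001, 1081),
    GroupEffect("G", -0.79, 0.030, 2763),
)


@dataclass(frozen=True)
class CohortSimParams:
    """Generative settings for a VON-shaped synthetic cohort.

    Gestational age at birth is uniform over 23 0/7 to 34 6/7 weeks (whole
    days).  Birth Z is normal (``birth_z_mean``, ``birth_z_sd``) truncated
    to +/-4; the delta-Z residual is normal with SD ``noise_sd``; both
    truncations resample so the planted group sizes survive the pipeline's
    own |Z| <= 4 exclusion untouched.  Discharge timing targets a normal
    postmenstrual age (``discharge_pma_mean``/``sd`` weeks) clipped to the
    chart domain, with a minimum stay of one week.
    """

    groups: tuple[GroupEffect, ...] = DEFAULT_HOSPITAL_EFFECTS
    center_weeks: float = 29.0
    ga_min_days: int = 23 * 7
    ga_max_days: int = 34 * 7 + 6
    birth_z_mean: float = -0.19
    birth_z_sd: float = 0.84
    noise_sd: float = 0.45
    discharge_pma_mean: float = 37.0
    discharge_pma_sd: float = 1.8
    birth_year_range: tuple[int, int] = (2006, 2011)
    max_retries: int = 100

    def __post_init__(self):
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")
        if not self.groups:
            raise UsageError("at least one group is required")


def _truncated_normal(rng, mean, sd, size, lo, hi, max_retries):
    """Normal draws resampled into [lo, hi] (exact truncation by rejection)."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise DomainError(f"degenerate draw {mean} outside [{lo}, {hi}]")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(max_retries):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise DomainError(
        f"could not draw values in [{lo}, {hi}] after {max_retries} retries"
    )


def simulate_cohort(
    params: CohortSimParams = CohortSimParams(),
    chart: ChartSpec | None = None,
    *,
    seed: int,
) -> pd.DataFrame:
    """Simulate a VON-dialect cohort with planted group delta-Z structure.

    Returns a DataFrame with the eNICQ column names (BYEAR, GAWEEKS,
    GADAYS, BWGT, LOS1, DWGT, LOCATE, DAYADMISS, FDISP, CMAL) plus HOSP.
    Weights are realised through the chart's quantile transform, so
    recomputing Z-scores from the emitted weights recovers the planted
    Z-scores exactly (up to float round-trip error).  Fully determined by
    ``seed``; the same seed yields byte-identical CSV output.
    """
    if chart is None:
        chart = make_chart()
    if chart.sex_specific:
        raise UsageError(
            "cohort simulation uses a non-sex-specific chart (registry "
            "exports carry no sex field)"
        )
    rng = np.random.default_rng(seed)
    days_per_unit = DAYS_PER_UNIT[chart.age_unit]
    dom_lo, dom_hi = chart.domain(None)
    dom_lo_days = dom_lo * days_per_unit
    dom_hi_days = dom_hi * days_per_unit
    if params.ga_min_days < dom_lo_days or params.ga_max_days > dom_hi_days:
        raise UsageError("gestational-age range not covered by the chart")

    frames = []
    from .charts import lms_at_many

    for grp in params.groups:
        n = grp.n
        ga_days = rng.integers(params.ga_min_days, params.ga_max_days + 1, n)
        ga_weeks = ga_days / 7.0
        z_birth = np.empty(n)
        z_dis = np.empty(n)
        pending = np.arange(n)
        mean_delta = grp.intercept + grp.slope * (ga_weeks - params.center_weeks)
        for _ in range(params.max_retries):
            m = pending.size
            if m == 0:
                break
            zb = _truncated_normal(
                rng, params.birth_z_mean, params.birth_z_sd, m, -4.0, 4.0,
                params.max_retries,
            )
            noise = rng.normal(0.0, params.noise_sd, m) if params.noise_sd else 0.0
            zd = zb + mean_delta[pending] + noise
            ok = np.abs(zd) <= 4.0
            z_birth[pending[ok]] = zb[ok]
            z_dis[pending[ok]] = zd[ok]
            pending = pending[~ok]
        if pending.size:
            raise DomainError(
                f"group {grp.label!r}: could not keep discharge Z within "
                f"+/-4 after {params.max_retries} rounds"
            )

        # discharge timing: clip the target PMA into the chart domain and
        # require at least a one-week stay
        pma_target = rng.normal(params.discharge_pma_mean,
                                params.discharge_pma_sd, n)
        lo = np.maximum(ga_weeks + 1.0, dom_lo_days / days_per_unit)
        hi = dom_hi_days / days_per_unit - 1e-9
        if np.any(lo > hi):
            raise DomainError("chart domain too narrow for any valid stay")
        pma_weeks = np.clip(pma_target, lo, hi)
        los = np.maximum(np.rint((pma_weeks - ga_weeks) * 7.0), 7).astype(int)
        pma_days = ga_days + los

        Lb, Mb, Sb = lms_at_many(chart, None, ga_days / days_per_unit)
        bwgt = z_to_x(z_birth, (Lb, Mb, Sb))
        Ld, Md, Sd = lms_at_many(chart, None, pma_days / days_per_unit)
        dwgt = z_to_x(z_dis, (Ld, Md, Sd))
        if np.isnan(bwgt).any() or np.isnan(dwgt).any():
            raise DomainError(
                f"group {grp.label!r}: simulated ages left the chart domain"
            )

        frames.append(
            pd.DataFrame(
                {
                    "HOSP": grp.label,
                    "BYEAR": rng.integers(params.birth_year_range[0],
                                          params.birth_year_range[1] + 1, n),
                    "GAWEEKS": ga_days // 7,
                    "GADAYS": ga_days % 7,
                    "BWGT": bwgt,
                    "LOS1": los,
                    "DWGT": dwgt,
                    "LOCATE": 1,
                    "DAYADMISS": 0,
                    "FDISP": 1,
                    "CMAL": 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
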