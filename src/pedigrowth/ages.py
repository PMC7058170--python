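"""Gestational, postmenstrual, chronologic and corrected age arithmetic.

All arithmetic is calendar-day counting on ``datetime.date`` objects (no
time of day, no time zones).  The obstetric convention of a 280-day
(40-week) interval from last menstrual period to due date anchors every
conversion: the gestational age on any date *d* is
``280 - (due_date - d)`` days.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

from .errors import ConsistencyError, DomainError, UsageError

__all__ = ["GestationalAge", "AgePair", "TERM_DAYS", "resolve_ga", "corrected_age"]

#: LMP-to-due-date interval: 40 completed weeks.
TERM_DAYS = 280


@dataclass(frozen=True, order=True)
class GestationalAge:
    """A gestational (or postmenstrual) age as completed weeks plus days.

    ``GestationalAge(30, 3)`` is the age clinicians write "30 3/7".
    """

    weeks: int
    days: int = 0

    def __post_init__(self):
        if self.weeks < 0:
            raise DomainError(f"weeks must be >= 0, got {self.weeks}")
        if not 0 <= self.days <= 6:
            raise DomainError(f"days must be in 0..6, got {self.days}")

    @property
    def total_days(self) -> int:
        return self.weeks * 7 + self.days

    @property
    def as_weeks(self) -> float:
        """Age in decimal weeks (total_days / 7)."""
        return self.total_days / 7.0

    @classmethod
    def from_days(cls, total_days: int) -> "GestationalAge":
        total_days = int(total_days)
        if total_days < 0:
            raise DomainError(f"gestational age cannot be negative ({total_days} days)")
        return cls(total_days // 7, total_days % 7)

    def __str__(self) -> str:
        return f"{self.weeks} {self.days}/7"


@dataclass(frozen=True)
class AgePair:
    """Chronologic age and the matching age corrected for prematurity.

    ``corrected = chronologic - (280 - GA-at-birth in days)``; it is
    negative before term-equivalent age (``before_term`` is then True).
    """

    chronologic_days: int
    corrected_days: int

    @property
    def before_term(self) -> bool:
        return self.corrected_days < 0


def _to_date(value, label: str) -> date:
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    if isinstance(value, str):
        try:
            return date.fromisoformat(value)
        except ValueError as exc:
            raise UsageError(f"{label} is not an ISO-8601 date: {value!r}") from exc
    raise UsageError(f"{label} must be a date or ISO-8601 string, got {value!r}")


def resolve_ga(
    *,
    last_menstrual_period=None,
    due_date=None,
    birth_date=None,
    ga_at_birth: GestationalAge | None = None,
    chronologic_age_days: int | None = None,
    target_date=None,
) -> GestationalAge:
    """Gestational/postmenstrual age on a target date from any sufficient
    combination of anchors.

    Sufficient anchors for the pregnancy timeline are: the last menstrual
    period alone; the due date alone; or the birth date together with the
    gestational age at birth.  The target date may be given directly, or as
    birth date plus a chronologic age in days.  If several redundant
    anchors are supplied they must agree exactly; any disagreement raises
    :class:`ConsistencyError` rather than silently preferring one input.
    """
    candidates: list[tuple[str, date]] = []
    if last_menstrual_period is not None:
        lmp = _to_date(last_menstrual_period, "last_menstrual_period")
        candidates.append(("last_menstrual_period", lmp + timedelta(days=TERM_DAYS)))
    if due_date is not None:
        candidates.append(("due_date", _to_date(due_date, "due_date")))
    birth = _to_date(birth_date, "birth_date") if birth_date is not None else None
    if birth is not None and ga_at_birth is not None:
        candidates.append(
            ("birth_date+ga_at_birth",
             birth + timedelta(days=TERM_DAYS - ga_at_birth.total_days))
        )
    if not candidates:
        raise UsageError(
            "insufficient inputs to anchor the pregnancy timeline: provide "
            "last_menstrual_period, or due_date, or birth_date together "
            "with ga_at_birth"
        )
    base_label, base_due = candidates[0]
    for label, cand in candidates[1:]:
        if cand != base_due:
            raise ConsistencyError(
                f"conflicting anchors: {base_label} implies due date "
                f"{base_due.isoformat()} but {label} implies "
                f"{cand.isoformat()}"
            )

    if target_date is not None:
        target = _to_date(target_date, "target_date")
    elif birth is not None and chronologic_age_days is not None:
        target = birth + timedelta(days=int(chronologic_age_days))
    else:
        raise UsageError(
            "insufficient inputs to fix the target date: provide "
            "target_date, or birth_date together with chronologic_age_days"
        )

    ga_days = TERM_DAYS - (base_due - target).days
    if ga_days < 0:
        raise DomainError(
            f"target date {target.isoformat()} precedes the last menstrual "
            "period implied by the anchors"
        )
    return GestationalAge.from_days(ga_days)


def corrected_age(ga_at_birth: GestationalAge, chronologic_days: int) -> AgePair:
    """Corrected (for prematurity) age alongside the chronologic age.

    The correction subtracts the gestational shortfall from 40 0/7 weeks;
    an infant born at term has corrected == chronologic.  Before
    term-equivalent age the corrected age is negative and returned as-is.
    """
    chronologic_days = int(chronologic_days)
    if chronologic_days < 0:
        raise DomainError(f"chronologic age must be >= 0, got {chronologic_days}")
    shortfall = TERM_DAYS - ga_at_birth.total_days
    return AgePair(chronologic_days, chronologic_days - shortfall)
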