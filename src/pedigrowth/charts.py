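"""Growth-reference tables: loading, validation, interpolation, centering.

A growth reference is a table of (sex, age, L, M, S) knots plus metadata:
the measure, the age unit of the table, whether the reference is
sex-specific, and a *centering offset* describing what each table age label
actually represents.  Published tables label rows by completed age interval
rather than by the interval's centre: a preterm chart row labelled "30
weeks" typically describes infants at 30 3/7 weeks (midweek centering), and
a monthly infant table row labelled "1 month" describes the half-month
point.  ``lms_at`` maps a subject's exact age into table coordinates by
subtracting the offset, then interpolates L, M and S *linearly and
component-wise* between the bracketing knots.  Ages outside the knot range
raise :class:`ChartRangeError`; no extrapolation is ever performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChartLoadError, ChartRangeError, UsageError
from .lms import LMSTriple

__all__ = [
    "ChartSpec",
    "PRESETS",
    "load_chart",
    "save_chart",
    "lms_at",
    "lms_at_many",
    "center_age",
]

log = logging.getLogger(__name__)

SEXES = ("male", "female", "unspecified")
AGE_UNITS = ("gestational_weeks", "gestational_days", "months")

#: mean-calendar-month convention: months <-> days uses 30.4375 d/month;
#: weeks use exactly 7 days.
DAYS_PER_UNIT = {
    "gestational_weeks": 7.0,
    "gestational_days": 1.0,
    "months": 30.4375,
}

MEASURES = (
    "weight",
    "length",
    "height",
    "head_circumference",
    "bmi",
    "arm_circumference",
    "triceps_skinfold",
    "subscapular_skinfold",
)

#: Metadata conventions for well-known chart families.  Only metadata is
#: shipped: the LMS parameter values themselves are loaded from files the
#: user supplies (or from the synthetic generator in :mod:`.simulate`).
#: Offsets are in the chart's native age unit.
PRESETS: dict[str, dict] = {
    # labelled in completed weeks, centred midweek (label w means w + 3/7)
    "fenton2003": dict(age_unit="gestational_weeks", centering_offset=3.0 / 7.0,
                       sex_specific=False),
    # daily resolution: no interpolation offset needed
    "fenton2013": dict(age_unit="gestational_days", centering_offset=0.0,
                       sex_specific=True),
    # monthly labels centred at the half-month point
    "cdc_infant": dict(age_unit="months", centering_offset=0.5, sex_specific=True),
    "cdc_pediatric": dict(age_unit="months", centering_offset=0.5, sex_specific=True),
    "who_infant": dict(age_unit="months", centering_offset=0.0, sex_specific=True),
    "olsen2010": dict(age_unit="gestational_weeks", centering_offset=0.0,
                      sex_specific=True),
}

_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male", "boy": "male",
    "female": "female", "f": "female", "2": "female", "girl": "female",
    "unspecified": "unspecified", "u": "unspecified", "": "unspecified",
    "0": "unspecified", "both": "unspecified",
}


def normalize_sex(sex) -> str:
    """Map common sex encodings (male/female/M/F/1/2/...) onto the canonical
    {male, female, unspecified} labels."""
    if sex is None:
        return "unspecified"
    if isinstance(sex, float) and np.isnan(sex):
        return "unspecified"
    key = str(sex).strip().lower()
    if key.endswith(".0"):
        key = key[:-2]
    if key not in _SEX_ALIASES:
        raise UsageError(f"unrecognised sex value {sex!r}")
    return _SEX_ALIASES[key]


@dataclass
class ChartSpec:
    """A validated growth reference: knot table plus its conventions.

    ``records`` holds one row per (sex, age) knot with columns
    ``sex, age, L, M, S``, strictly increasing in age within each sex.
    ``centering_offset`` is what must be *added* to a table label to get the
    exact age it represents (so exact ages are mapped to table coordinates
    by subtraction).
    """

    name: str
    measure: str
    age_unit: str
    sex_specific: bool
    centering_offset: float
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ChartLoadError(f"unknown measure {self.measure!r}")
        if self.age_unit not in AGE_UNITS:
            raise ChartLoadError(f"unknown age unit {self.age_unit!r}")
        self.records = _validate_records(self.records, self.sex_specific)

    # -- introspection -------------------------------------------------
    def sexes(self) -> tuple[str, ...]:
        return tuple(self.records["sex"].unique())

    def knots(self, sex=None) -> pd.DataFrame:
        """The knot rows for one sex table (label coordinates)."""
        s = self._table_sex(sex)
        return self.records[self.records["sex"] == s]

    def age_bounds(self, sex=None) -> tuple[float, float]:
        """(min, max) knot ages in *table label* coordinates."""
        ages = self.knots(sex)["age"].to_numpy()
        return float(ages[0]), float(ages[-1])

    def domain(self, sex=None) -> tuple[float, float]:
        """(min, max) *exact* subject ages covered, in native units."""
        lo, hi = self.age_bounds(sex)
        return lo + self.centering_offset, hi + self.centering_offset

    def _table_sex(self, sex) -> str:
        s = normalize_sex(sex)
        if self.sex_specific:
            if s == "unspecified":
                raise UsageError(
                    f"chart {self.name!r} is sex-specific; sex must be "
                    "male or female"
                )
            return s
        if s != "unspecified":
            log.info(
                "chart %r is not sex-specific; ignoring sex=%r", self.name, s
            )
        return "unspecified"


def _validate_records(df: pd.DataFrame, sex_specific: bool) -> pd.DataFrame:
    required = ["sex", "age", "L", "M", "S"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ChartLoadError(f"records missing column(s): {', '.join(missing)}")
    df = df[required].copy()
    df["sex"] = [normalize_sex(s) for s in df["sex"]]
    for col in ("age", "L", "M", "S"):
        parsed = np.empty(len(df))
        for i, raw in enumerate(df[col]):
            try:
                # Python's strtod round-trips repr output exactly, which
                # pandas' fast parser does not guarantee
                parsed[i] = float(raw)
            except (TypeError, ValueError):
                parsed[i] = np.nan
            if not np.isfinite(parsed[i]):
                raise ChartLoadError(
                    f"row {i + 1}: unparseable or missing {col!r} value "
                    f"{raw!r}"
                )
        df[col] = parsed
    if (df["M"] <= 0).any():
        row = int(np.flatnonzero((df["M"] <= 0).to_numpy())[0])
        raise ChartLoadError(f"row {row + 1}: M must be > 0, got {df['M'].iloc[row]}")
    if (df["S"] <= 0).any():
        row = int(np.flatnonzero((df["S"] <= 0).to_numpy())[0])
        raise ChartLoadError(f"row {row + 1}: S must be > 0, got {df['S'].iloc[row]}")
    if (~np.isfinite(df["L"])).any():
        row = int(np.flatnonzero((~np.isfinite(df["L"])).to_numpy())[0])
        raise ChartLoadError(f"row {row + 1}: L must be finite")
    dup = df.duplicated(subset=["sex", "age"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ChartLoadError(
            f"row {row + 1}: duplicate knot (sex={df['sex'].iloc[row]}, "
            f"age={df['age'].iloc[row]})"
        )
    present = set(df["sex"].unique())
    if sex_specific:
        if present != {"male", "female"}:
            raise ChartLoadError(
                "sex-specific chart must provide male and female tables, "
                f"found {sorted(present)}"
            )
    else:
        if len(present) != 1:
            raise ChartLoadError(
                "non-sex-specific chart must carry a single table, "
                f"found sexes {sorted(present)}"
            )
        if present != {"unspecified"}:
            df["sex"] = "unspecified"
    df = df.sort_values(["sex", "age"], kind="mergesort").reset_index(drop=True)
    n_knots = df.groupby("sex")["age"].count()
    if (n_knots < 2).any():
        raise ChartLoadError("each sex table needs at least 2 knots")
    return df


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, str) and "\n" in source:
        source = StringIO(source)
    try:
        return pd.read_csv(source, dtype=str, skipinitialspace=True)
    except Exception as exc:  # noqa: BLE001 - rewrap any parse failure
        raise ChartLoadError(f"could not read chart table: {exc}") from exc


def load_chart(
    source,
    *,
    name: str,
    measure: str,
    preset: str | None = None,
    age_unit: str | None = None,
    sex_specific: bool | None = None,
    centering_offset: float | None = None,
) -> ChartSpec:
    """Load a growth-reference LMS table from delimited text.

    Two header dialects are accepted and auto-detected:

    * canonical: ``sex,age,L,M,S`` with sex in {male, female, unspecified};
    * the published CDC LMS data-file dialect: a numeric ``Sex`` code
      (1 = male, 2 = female) and an age column named ``Agemos`` (months).

    ``preset`` fills the metadata (age unit, sex handling, centering
    convention) for known chart families; explicit keyword arguments
    override the preset.  Rows failing validation (non-numeric values,
    M <= 0, S <= 0, duplicate knots) raise :class:`ChartLoadError` naming
    the offending data row.
    """
    meta: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise UsageError(
                f"unknown preset {preset!r}; known: {sorted(PRESETS)}"
            )
        meta.update(PRESETS[preset])
    raw = _read_table(source)
    raw.columns = [str(c).strip() for c in raw.columns]
    lower = {c.lower(): c for c in raw.columns}

    if "agemos" in lower:  # CDC data-file dialect
        colmap = {lower["agemos"]: "age"}
        meta.setdefault("age_unit", "months")
        meta.setdefault("sex_specific", True)
        meta.setdefault("centering_offset", PRESETS["cdc_infant"]["centering_offset"])
    else:
        if "age" not in lower:
            raise ChartLoadError(
                "no age column found (expected 'age' or CDC-style 'Agemos')"
            )
        colmap = {lower["age"]: "age"}
    for want in ("sex", "l", "m", "s"):
        if want not in lower:
            raise ChartLoadError(f"missing column {want!r}")
        colmap[lower[want]] = want.upper() if want in ("l", "m", "s") else want
    df = raw.rename(columns=colmap)

    if age_unit is not None:
        meta["age_unit"] = age_unit
    if sex_specific is not None:
        meta["sex_specific"] = sex_specific
    if centering_offset is not None:
        meta["centering_offset"] = centering_offset
    meta.setdefault("age_unit", "months")
    meta.setdefault("centering_offset", 0.0)
    if "sex_specific" not in meta:
        try:
            sexes = {normalize_sex(s) for s in df["sex"]}
        except UsageError as exc:
            raise ChartLoadError(str(exc)) from exc
        meta["sex_specific"] = sexes == {"male", "female"}

    return ChartSpec(
        name=name,
        measure=measure,
        age_unit=meta["age_unit"],
        sex_specific=meta["sex_specific"],
        centering_offset=float(meta["centering_offset"]),
        records=df,
    )


def save_chart(chart: ChartSpec, path=None) -> str | None:
    """Serialise a chart's knots to the canonical ``sex,age,L,M,S`` CSV.

    Floats are written with ``repr`` (shortest round-trip form), so loading
    the output reproduces the numeric content bit-for-bit.
    """
    lines = ["sex,age,L,M,S"]
    for row in chart.records.itertuples(index=False):
        lines.append(
            f"{row.sex},{row.age!r},{row.L!r},{row.M!r},{row.S!r}"
        )
    text = "\n".join(lines) + "\n"
    if path is None:
        return text
    Path(path).write_text(text)
    return None


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def center_age(chart: ChartSpec, raw_age: float) -> float:
    """Map an exact subject age onto the chart's table-label coordinate."""
    return raw_age - chart.centering_offset


def lms_at(chart: ChartSpec, sex, age: float) -> LMSTriple:
    """Interpolated (L, M, S) at an exact subject age in native units.

    Exact knot ages return the stored triple unchanged; intermediate ages
    return the component-wise linear interpolation between the two
    bracketing knots.  Ages outside the knot range raise
    :class:`ChartRangeError`.
    """
    sub = chart.knots(sex)
    coord = center_age(chart, float(age))
    ages = sub["age"].to_numpy()
    if not (ages[0] <= coord <= ages[-1]):
        lo, hi = chart.domain(sex)
        raise ChartRangeError(
            f"age {age} ({chart.age_unit}) outside chart {chart.name!r} "
            f"domain [{lo:g}, {hi:g}]; extrapolation is not supported"
        )
    idx = int(np.searchsorted(ages, coord))
    if idx < len(ages) and ages[idx] == coord:
        row = sub.iloc[idx]
        return LMSTriple(float(row["L"]), float(row["M"]), float(row["S"]))
    return LMSTriple(
        float(np.interp(coord, ages, sub["L"].to_numpy())),
        float(np.interp(coord, ages, sub["M"].to_numpy())),
        float(np.interp(coord, ages, sub["S"].to_numpy())),
    )


def lms_at_many(chart: ChartSpec, sex, ages) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`lms_at` over an array of exact ages (single sex).

    Returns (L, M, S) arrays; out-of-domain ages yield NaN rather than
    raising, so cohort pipelines can tally them separately.
    """
    sub = chart.knots(sex)
    coord = np.asarray(ages, dtype=float) - chart.centering_offset
    knot_ages = sub["age"].to_numpy()
    out_of_range = ~((coord >= knot_ages[0]) & (coord <= knot_ages[-1]))
    Ls = np.interp(coord, knot_ages, sub["L"].to_numpy())
    Ms = np.interp(coord, knot_ages, sub["M"].to_numpy())
    Ss = np.interp(coord, knot_ages, sub["S"].to_numpy())
    for arr in (Ls, Ms, Ss):
        arr[out_of_range] = np.nan
    return Ls, Ms, Ss
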