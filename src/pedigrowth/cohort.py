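"""Registry-scale birth-to-discharge growth analysis.

Workflow: import a VON-style (Vermont Oxford Network eNICQ) patient-level
export, apply the eligibility filter, compute each infant's weight Z-score
at birth and at discharge on a preterm reference, and model the change
``delta_z = z_discharge - z_birth`` as a linear function of gestational age
at birth with full per-group (hospital or epoch) intercept and slope
interactions, centred at 29 0/7 weeks.

Eligibility: gestational age 23 0/7 to 34 6/7 weeks; survival to
discharge; no severe congenital malformation; birth weight, discharge
weight and length of stay present; and both weight Z-scores within
[-4, +4] (values strictly beyond +/-4 usually reflect data-entry error and
are excluded; exactly -4 or +4 is retained).  Exclusions are tallied by
the *first* failing criterion in a fixed order so reports are stable.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .ages import GestationalAge
from .charts import DAYS_PER_UNIT, ChartSpec, lms_at
from .errors import ChartRangeError, GrowthError, ModelFitError, UsageError
from .lms import x_to_z

__all__ = [
    "CohortRecord",
    "DeltaZModelFit",
    "recode_von",
    "compute_delta_z",
    "apply_eligibility",
    "fit_delta_z_model",
    "summarize_by_group",
    "compare_groups_tukey",
    "records_to_frame",
    "EXCLUSION_ORDER",
]

GA_MIN_DAYS = 23 * 7           # 23 0/7
GA_MAX_DAYS = 34 * 7 + 6       # 34 6/7
Z_LIMIT = 4.0

#: fixed first-reason attribution order for exclusion tallies
EXCLUSION_ORDER = (
    "ga_range",
    "death",
    "disposition",
    "malformation",
    "missing_fields",
    "z_range",
    "chart_range",
)

_DISPOSITION_CODES = {
    "1": "home", "home": "home",
    "2": "transfer", "transfer": "transfer", "transferred": "transfer",
    "3": "death", "death": "death", "died": "death", "deceased": "death",
}


@dataclass
class CohortRecord:
    """One infant's registry-derived fields plus derived Z quantities."""

    hospital: str = "unknown"
    birth_year: int | None = None
    ga_birth: GestationalAge | None = None
    birth_weight: float | None = None
    los_days: int | None = None
    discharge_weight: float | None = None
    disposition: str = "other"
    inborn: bool | None = None
    admit_day: int | None = None
    malformation: bool = False
    z_birth: float | None = None
    z_discharge: float | None = None
    delta_z: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def pma_discharge(self) -> GestationalAge | None:
        """Postmenstrual age at discharge: GA at birth + length of stay."""
        if self.ga_birth is None or self.los_days is None:
            return None
        return GestationalAge.from_days(self.ga_birth.total_days + self.los_days)


# ---------------------------------------------------------------------------
# VON import
# ---------------------------------------------------------------------------

def _parse_num(value):
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "null", "."):
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _row_to_record(row: dict, hospital: str | None, flags_out: Counter) -> CohortRecord:
    rec = CohortRecord()
    flags = rec.flags
    rec.hospital = str(
        row.get("HOSP") or row.get("HOSPITAL") or hospital or "unknown"
    ).strip()

    byear = _parse_num(row.get("BYEAR"))
    rec.birth_year = int(byear) if byear is not None else None

    gaw = _parse_num(row.get("GAWEEKS"))
    gad = _parse_num(row.get("GADAYS"))
    if gaw is None:
        flags.append("missing_ga")
    else:
        try:
            rec.ga_birth = GestationalAge(int(gaw), int(gad) if gad is not None else 0)
        except GrowthError:
            flags.append("invalid_ga")

    rec.birth_weight = _parse_num(row.get("BWGT"))
    if rec.birth_weight is None:
        flags.append("missing_birth_weight")
    rec.discharge_weight = _parse_num(row.get("DWGT"))
    if rec.discharge_weight is None:
        flags.append("missing_discharge_weight")
    los = _parse_num(row.get("LOS1"))
    if los is None:
        flags.append("missing_los")
    else:
        rec.los_days = int(los)

    disp_raw = row.get("FDISP")
    disp_key = str(disp_raw).strip().lower() if disp_raw is not None else ""
    if disp_key.endswith(".0"):
        disp_key = disp_key[:-2]
    rec.disposition = _DISPOSITION_CODES.get(disp_key, "other")

    locate = _parse_num(row.get("LOCATE"))
    if locate is not None:
        rec.inborn = int(locate) == 1
    elif str(row.get("LOCATE") or "").strip().lower() in ("inborn", "outborn"):
        rec.inborn = str(row["LOCATE"]).strip().lower() == "inborn"

    admit = _parse_num(row.get("DAYADMISS"))
    rec.admit_day = int(admit) if admit is not None else None

    cmal = row.get("CMAL")
    cmal_s = str(cmal).strip().lower() if cmal is not None else ""
    rec.malformation = cmal_s not in ("", "0", "0.0", "no", "none", "nan", "na")

    for f in flags:
        flags_out[f] += 1
    return rec


def _rows_from_source(source) -> list[dict]:
    """Read CSV / XML / JSON VON exports into a list of field dicts."""
    if isinstance(source, pd.DataFrame):
        return source.to_dict(orient="records")
    text: str | None = None
    if isinstance(source, (str, Path)):
        looks_inline = isinstance(source, str) and (
            "\n" in source or source.lstrip()[:1] in ("[", "{", "<")
        )
        if looks_inline:
            text = source
        else:
            p = Path(source)
            if not p.exists():
                raise UsageError(f"no such file: {source}")
            text = p.read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        raise UsageError(f"unsupported VON source {type(source).__name__}")
    stripped = text.lstrip()
    if stripped.startswith("<"):
        root = ElementTree.fromstring(text)
        rows = []
        for el in root:
            row = dict(el.attrib)
            for child in el:
                row[child.tag] = child.text
            rows.append(row)
        return rows
    if stripped.startswith("[") or stripped.startswith("{"):
        data = json.loads(text)
        if isinstance(data, dict):
            data = data.get("records") or data.get("patients") or [data]
        return list(data)
    df = pd.read_csv(StringIO(text), dtype=str, skipinitialspace=True)
    if df.columns.size == 0:
        raise UsageError("VON file has no header row")
    return df.to_dict(orient="records")


def recode_von(source, *, hospital: str | None = None):
    """Import a VON-dialect export (CSV, XML or JSON) into cohort records.

    Field names follow the eNICQ convention: BYEAR, GAWEEKS, GADAYS, BWGT,
    LOS1, DWGT, LOCATE, DAYADMISS, FDISP, CMAL, plus an optional HOSP
    column (otherwise pass ``hospital=``).  Unparseable or missing required
    fields flag the record rather than dropping it; the returned report
    counts every flag reason.

    Returns
    -------
    (records, report)
        ``records`` is a list of :class:`CohortRecord`; ``report`` a dict
        with ``n_rows``, ``n_complete``, ``n_flagged`` and per-reason
        ``flags`` counts.
    """
    rows = _rows_from_source(source)
    if not rows:
        raise UsageError("VON source contains no records")
    # normalise field-name case once
    flags = Counter()
    records = []
    for row in rows:
        row = {str(k).strip().upper(): v for k, v in row.items()}
        records.append(_row_to_record(row, hospital, flags))
    n_flagged = sum(1 for r in records if r.flags)
    report = {
        "n_rows": len(records),
        "n_complete": len(records) - n_flagged,
        "n_flagged": n_flagged,
        "flags": dict(flags),
    }
    return records, report


# ---------------------------------------------------------------------------
# derived quantities and eligibility
# ---------------------------------------------------------------------------

def _age_native(chart: ChartSpec, days: float) -> float:
    return days / DAYS_PER_UNIT[chart.age_unit]


def compute_delta_z(record: CohortRecord, chart: ChartSpec) -> CohortRecord:
    """Fill in z_birth, z_discharge and delta_z for one record.

    A postmenstrual age outside the chart's knot range flags the record
    ``chart_range`` instead of raising, so downstream filtering can tally
    it; other per-record problems likewise never raise.
    """
    rec = replace(record, flags=list(record.flags))
    if (rec.ga_birth is None or rec.birth_weight is None
            or rec.discharge_weight is None or rec.los_days is None):
        return rec
    try:
        lms_b = lms_at(chart, None, _age_native(chart, rec.ga_birth.total_days))
        rec.z_birth = x_to_z(rec.birth_weight, lms_b)
        lms_d = lms_at(
            chart, None, _age_native(chart, rec.pma_discharge.total_days)
        )
        rec.z_discharge = x_to_z(rec.discharge_weight, lms_d)
        rec.delta_z = rec.z_discharge - rec.z_birth
    except ChartRangeError:
        if "chart_range" not in rec.flags:
            rec.flags.append("chart_range")
    except GrowthError as exc:
        rec.flags.append(f"z_error:{exc}")
    return rec


def _first_exclusion(rec: CohortRecord, *, exclude_transfers: bool,
                     require_home_discharge: bool) -> str | None:
    if rec.ga_birth is not None and not (
        GA_MIN_DAYS <= rec.ga_birth.total_days <= GA_MAX_DAYS
    ):
        return "ga_range"
    if rec.disposition == "death":
        return "death"
    if require_home_discharge and rec.disposition != "home":
        return "disposition"
    if exclude_transfers and rec.disposition == "transfer":
        return "disposition"
    if rec.malformation:
        return "malformation"
    if (rec.ga_birth is None or rec.birth_weight is None
            or rec.discharge_weight is None or rec.los_days is None):
        return "missing_fields"
    if "chart_range" in rec.flags:
        return "chart_range"
    if rec.z_birth is None or rec.z_discharge is None:
        return "chart_range"
    if abs(rec.z_birth) > Z_LIMIT or abs(rec.z_discharge) > Z_LIMIT:
        return "z_range"
    return None


def apply_eligibility(
    records,
    chart: ChartSpec,
    *,
    exclude_transfers: bool = False,
    require_home_discharge: bool = False,
):
    """Filter records by the study eligibility rules.

    Derived Z quantities are computed (via :func:`compute_delta_z`) for any
    record still missing them.  Returns ``(eligible, report)`` where the
    report tallies exclusions by first failing criterion in the fixed
    order: ga_range, death, disposition (only when the optional transfer /
    home-discharge filters are on), malformation, missing_fields, z_range,
    chart_range.  Survival to discharge is always required; the stricter
    disposition filters are optional because registry populations differ
    in transfer practice.
    """
    eligible = []
    tallies = Counter()
    for rec in records:
        if rec.delta_z is None and "chart_range" not in rec.flags:
            rec = compute_delta_z(rec, chart)
        reason = _first_exclusion(
            rec,
            exclude_transfers=exclude_transfers,
            require_home_discharge=require_home_discharge,
        )
        if reason is None:
            eligible.append(rec)
        else:
            tallies[reason] += 1
    report = {
        "n_input": len(records) if hasattr(records, "__len__") else None,
        "n_eligible": len(eligible),
        "excluded": {k: tallies[k] for k in EXCLUSION_ORDER if tallies[k]},
    }
    return eligible, report


def records_to_frame(records) -> pd.DataFrame:
    """Flatten cohort records into an analysis DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "hospital": r.hospital,
                "birth_year": r.birth_year,
                "ga_weeks": r.ga_birth.as_weeks if r.ga_birth else np.nan,
                "birth_weight": r.birth_weight,
                "los_days": r.los_days,
                "discharge_weight": r.discharge_weight,
                "pma_discharge_weeks": (
                    r.pma_discharge.as_weeks if r.pma_discharge else np.nan
                ),
                "disposition": r.disposition,
                "z_birth": r.z_birth,
                "z_discharge": r.z_discharge,
                "delta_z": r.delta_z,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# modelling
# ---------------------------------------------------------------------------

@dataclass
class DeltaZModelFit:
    """A per-group delta-Z regression: one line per group, fitted jointly.

    ``groups`` has one row per group with the intercept (the expected
    delta-Z at the centering gestational age), the slope (delta-Z per week
    of gestational age at birth), classical OLS standard errors, 95% CIs,
    two-sided p-values, and n.  When a reference group is designated,
    ``contrasts`` carries the difference-from-reference estimates for the
    remaining groups.
    """

    groups: pd.DataFrame
    resid_sd: float
    center_weeks: float
    nobs: int
    reference: str | None = None
    contrasts: pd.DataFrame | None = None
    result: object = field(default=None, repr=False)


def _model_frame(records, group_attr: str) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "group" not in df.columns:
            if group_attr in df.columns:
                df = df.rename(columns={group_attr: "group"})
            else:
                raise UsageError(
                    f"DataFrame needs a 'group' or {group_attr!r} column"
                )
        need = {"delta_z", "ga_weeks"}
        missing = need - set(df.columns)
        if missing:
            raise UsageError(f"DataFrame missing column(s) {sorted(missing)}")
        return df[["group", "ga_weeks", "delta_z"]]
    rows = [
        {
            "group": getattr(r, group_attr),
            "ga_weeks": r.ga_birth.as_weeks,
            "delta_z": r.delta_z,
        }
        for r in records
        if r.delta_z is not None and r.ga_birth is not None
    ]
    if not rows:
        raise UsageError("no records with delta_z available to fit")
    return pd.DataFrame(rows)


def fit_delta_z_model(
    records,
    *,
    group_attr: str = "hospital",
    center_weeks: float = 29.0,
    reference: str | None = None,
    alpha: float = 0.05,
) -> DeltaZModelFit:
    """OLS fit of delta-Z on centred gestational age with full per-group
    intercept and slope interactions.

    The design is the saturated interaction model — an indicator and an
    indicator-by-(ga - center) column per group — so each group gets its
    own line while sharing a single residual variance.  The intercept for
    a group is therefore exactly its predicted delta-Z at the centering
    gestational age (29 0/7 weeks by default).

    ``records`` may be a list of :class:`CohortRecord` or a DataFrame with
    columns ``group`` (or ``group_attr``), ``ga_weeks`` and ``delta_z``.
    A group with fewer than 2 records, or with a single distinct
    gestational age, makes the design singular and raises
    :class:`ModelFitError` naming the group.
    """
    df = _model_frame(records, group_attr)
    df = df.dropna(subset=["group", "ga_weeks", "delta_z"])
    groups = sorted(df["group"].astype(str).unique())
    if df["ga_weeks"].nunique() < 2:
        raise ModelFitError("need at least 2 distinct gestational ages overall")
    counts = df.groupby(df["group"].astype(str))["delta_z"].count()
    ga_counts = df.groupby(df["group"].astype(str))["ga_weeks"].nunique()
    for g in groups:
        if counts[g] < 2:
            raise ModelFitError(f"group {g!r} has fewer than 2 records")
        if ga_counts[g] < 2:
            raise ModelFitError(
                f"group {g!r} has a single gestational age; its slope is "
                "not identifiable"
            )
    ga_c = df["ga_weeks"].to_numpy() - center_weeks
    glabels = df["group"].astype(str).to_numpy()
    X = pd.DataFrame(index=df.index)
    for g in groups:
        ind = (glabels == g).astype(float)
        X[f"intercept[{g}]"] = ind
        X[f"slope[{g}]"] = ind * ga_c
    res = sm.OLS(df["delta_z"].to_numpy(), X).fit()
    ci = res.conf_int(alpha=alpha)
    rows = []
    for g in groups:
        ik, sk = f"intercept[{g}]", f"slope[{g}]"
        rows.append(
            {
                "group": g,
                "n": int(counts[g]),
                "intercept": res.params[ik],
                "intercept_se": res.bse[ik],
                "intercept_ci_low": ci.loc[ik, 0],
                "intercept_ci_high": ci.loc[ik, 1],
                "intercept_p": res.pvalues[ik],
                "slope": res.params[sk],
                "slope_se": res.bse[sk],
                "slope_ci_low": ci.loc[sk, 0],
                "slope_ci_high": ci.loc[sk, 1],
                "slope_p": res.pvalues[sk],
            }
        )
    gdf = pd.DataFrame(rows).set_index("group")

    contrasts = None
    if reference is not None:
        ref = str(reference)
        if ref not in groups:
            raise UsageError(f"reference group {reference!r} not in data")
        Xr = pd.DataFrame(index=df.index)
        Xr["intercept"] = 1.0
        Xr["slope"] = ga_c
        for g in groups:
            if g == ref:
                continue
            ind = (glabels == g).astype(float)
            Xr[f"intercept_diff[{g}]"] = ind
            Xr[f"slope_diff[{g}]"] = ind * ga_c
        res_r = sm.OLS(df["delta_z"].to_numpy(), Xr).fit()
        ci_r = res_r.conf_int(alpha=alpha)
        crows = []
        for g in groups:
            if g == ref:
                continue
            ik, sk = f"intercept_diff[{g}]", f"slope_diff[{g}]"
            crows.append(
                {
                    "group": g,
                    "intercept_diff": res_r.params[ik],
                    "intercept_diff_se": res_r.bse[ik],
                    "intercept_diff_ci_low": ci_r.loc[ik, 0],
                    "intercept_diff_ci_high": ci_r.loc[ik, 1],
                    "intercept_diff_p": res_r.pvalues[ik],
                    "slope_diff": res_r.params[sk],
                    "slope_diff_se": res_r.bse[sk],
                    "slope_diff_ci_low": ci_r.loc[sk, 0],
                    "slope_diff_ci_high": ci_r.loc[sk, 1],
                    "slope_diff_p": res_r.pvalues[sk],
                }
            )
        contrasts = pd.DataFrame(crows).set_index("group")

    return DeltaZModelFit(
        groups=gdf,
        resid_sd=float(np.sqrt(res.mse_resid)),
        center_weeks=float(center_weeks),
        nobs=int(res.nobs),
        reference=str(reference) if reference is not None else None,
        contrasts=contrasts,
        result=res,
    )


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def summarize_by_group(records, *, group_attr: str = "hospital") -> pd.DataFrame:
    """Descriptive table: one row per group plus a combined ``all`` row.

    Columns: n; median and IQR of gestational age (weeks) and birth weight;
    mean and SD of birth Z, discharge Z and delta-Z; mean and SD of
    discharge postmenstrual age (weeks).  SDs are sample SDs and reported
    as missing (NaN) for single-record groups.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if group_attr in df.columns and group_attr != "group":
        df = df.rename(columns={group_attr: "group"})
    if df.empty:
        raise UsageError("no records to summarise")

    def _one(sub: pd.DataFrame) -> dict:
        q = sub["ga_weeks"].quantile([0.25, 0.5, 0.75])
        qb = sub["birth_weight"].quantile([0.25, 0.5, 0.75])
        return {
            "n": int(len(sub)),
            "ga_weeks_median": q[0.5],
            "ga_weeks_q1": q[0.25],
            "ga_weeks_q3": q[0.75],
            "birth_weight_median": qb[0.5],
            "birth_weight_q1": qb[0.25],
            "birth_weight_q3": qb[0.75],
            "z_birth_mean": sub["z_birth"].mean(),
            "z_birth_sd": sub["z_birth"].std(ddof=1),
            "z_discharge_mean": sub["z_discharge"].mean(),
            "z_discharge_sd": sub["z_discharge"].std(ddof=1),
            "delta_z_mean": sub["delta_z"].mean(),
            "delta_z_sd": sub["delta_z"].std(ddof=1),
            "pma_discharge_weeks_mean": sub["pma_discharge_weeks"].mean(),
            "pma_discharge_weeks_sd": sub["pma_discharge_weeks"].std(ddof=1),
        }

    rows = {}
    for g, sub in df.groupby(df["group"].astype(str)):
        if sub.empty:
            continue
        rows[g] = _one(sub)
    out = pd.DataFrame(rows).T
    out.loc["all"] = _one(df)
    out["n"] = out["n"].astype(int)
    out.index.name = "group"
    return out


def compare_groups_tukey(records, *, group_attr: str = "hospital",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise comparison of group mean delta-Z with Tukey's honestly
    significant difference (studentized-range) adjustment."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if group_attr in df.columns and group_attr != "group":
        df = df.rename(columns={group_attr: "group"})
    df = df.dropna(subset=["delta_z", "group"])
    res = pairwise_tukeyhsd(df["delta_z"].to_numpy(),
                            df["group"].astype(str).to_numpy(), alpha=alpha)
    table = res.summary()
    return pd.DataFrame(table.data[1:], columns=table.data[0])
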