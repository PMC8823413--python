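"""Cohort assembly for a CN-to-MCI conversion study.

Reads longitudinal visit tables and baseline covariate tables, derives
per-participant time-to-conversion outcomes with a first-hit definition
(time to the first MCI diagnosis; non-converters censored at their last
visit), applies the study's inclusion and exclusion filters, stratifies
by sex and computes standardized-difference covariate balance.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    DegenerateInputError,
    FormatError,
    InputError,
    RowParseError,
)

__all__ = [
    "Diagnosis",
    "VisitRecord",
    "BaselineProfile",
    "SurvivalRecord",
    "Exclusion",
    "VisitTableSpec",
    "TRACKED_FACTORS",
    "read_visits",
    "read_baseline",
    "derive_conversion",
    "derive_outcomes",
    "apply_inclusion",
    "SexCohorts",
    "standardized_difference",
    "balance_table",
]

#: Candidate risk factors tracked at baseline; denominator of the
#: per-participant missing-variable rate.
TRACKED_FACTORS = (
    "age",
    "race",
    "education",
    "apoe4_carrier",
    "family_history_dementia",
    "mmse",
    "cdr_global",
    "systolic_bp",
    "diastolic_bp",
)

#: Global CDR values accepted as valid codes; anything else is an
#: abnormal entry and the participant is excluded.
ALLOWED_CDR = (0.0, 0.5, 1.0, 2.0, 3.0)


class Diagnosis(str, Enum):
    CN = "CN"
    MCI = "MCI"
    AD = "AD"
    OTHER = "OTHER"


@dataclass(frozen=True)
class VisitRecord:
    """One participant-visit: months since baseline plus the diagnosis made."""

    participant_id: str
    month: int
    diagnosis: Diagnosis

    def __post_init__(self):
        if self.month < 0:
            raise InputError(f"visit month must be >= 0, got {self.month}")


@dataclass
class BaselineProfile:
    """Baseline covariates for one participant; ``None`` marks a missing value."""

    participant_id: str
    age: float
    sex: str  # "female" | "male"
    education: float | None = None
    apoe4_carrier: bool | None = None
    family_history_dementia: bool | None = None
    mmse: float | None = None
    cdr_global: float | None = None
    systolic_bp: float | None = None
    diastolic_bp: float | None = None
    race: str | None = None

    def __post_init__(self):
        if self.age is None:
            raise InputError(f"{self.participant_id}: age is required")
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise InputError(f"{self.participant_id}: MMSE {self.mmse} outside [0, 30]")

    def missing_rate(self, tracked: Sequence[str] = TRACKED_FACTORS) -> float:
        """Fraction of tracked candidate risk factors that are missing."""
        missing = sum(getattr(self, name) is None for name in tracked)
        return missing / len(tracked)

    def covariates(self) -> dict[str, float]:
        """Numeric encodings used for model fitting and scoring.

        Continuous factors pass through; booleans become 0/1; MMSE and CDR
        additionally get the indicator codings used by the point system
        (``mmse_le26``, ``cdr05``).  Missing values encode as ``nan``.
        """

        def num(v):
            return np.nan if v is None else float(v)

        cov = {
            "age": num(self.age),
            "education": num(self.education),
            "apoe4": num(self.apoe4_carrier),
            "fhd": num(self.family_history_dementia),
            "mmse": num(self.mmse),
            "cdr": num(self.cdr_global),
            "sbp": num(self.systolic_bp),
            "dbp": num(self.diastolic_bp),
        }
        cov["mmse_le26"] = np.nan if self.mmse is None else float(self.mmse <= 26)
        cov["cdr05"] = np.nan if self.cdr_global is None else float(self.cdr_global == 0.5)
        return cov


@dataclass
class SurvivalRecord:
    """Per-participant time-to-event outcome in years.

    ``event`` is true when the participant converted to MCI; otherwise the
    time is the censoring time at the last CN visit.
    """

    participant_id: str
    sex: str | None
    time: float
    event: bool
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.time > 0:
            raise InputError(f"{self.participant_id}: time must be > 0, got {self.time}")


@dataclass(frozen=True)
class Exclusion:
    participant_id: str
    reason: str


# ---------------------------------------------------------------------------
# Table reading


@dataclass
class VisitTableSpec:
    """Column map for a longitudinal visit CSV.

    The default dialect matches the package's own synthetic exports; use
    :meth:`adni_dialect` for DXSUM-style tables.
    """

    id_col: str = "participant_id"
    month_col: str = "month"
    diagnosis_col: str = "diagnosis"
    diagnosis_map: dict[str, str] = field(
        default_factory=lambda: {
            "CN": "CN", "NL": "CN", "1": "CN",
            "MCI": "MCI", "2": "MCI",
            "AD": "AD", "DEMENTIA": "AD", "3": "AD",
        }
    )
    missing_values: tuple[str, ...] = ("", "NA", "NaN", "-4", "-1")

    @classmethod
    def adni_dialect(cls) -> "VisitTableSpec":
        return cls(id_col="RID", month_col="M", diagnosis_col="DXCURREN")

    @classmethod
    def from_yaml(cls, path) -> "VisitTableSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "diagnosis_map" in known:
            known["diagnosis_map"] = {str(k).upper(): v for k, v in known["diagnosis_map"].items()}
        if "missing_values" in known:
            known["missing_values"] = tuple(str(v) for v in known["missing_values"])
        return cls(**known)


def read_visits(path, spec: VisitTableSpec | None = None) -> list[VisitRecord]:
    """Parse a visit CSV into :class:`VisitRecord` objects, sorted by id and month.

    Unknown diagnosis strings map to ``OTHER`` with a warning; a missing
    mandatory column raises :class:`FormatError` and an unparseable month
    raises :class:`RowParseError` carrying the row index.
    """
    spec = spec or VisitTableSpec()
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    for col in (spec.id_col, spec.month_col, spec.diagnosis_col):
        if col not in df.columns:
            raise FormatError(f"visit table lacks mandatory column {col!r}")

    records: list[VisitRecord] = []
    unknown: Counter[str] = Counter()
    for idx, row in enumerate(df.itertuples(index=False)):
        raw_month = str(row[df.columns.get_loc(spec.month_col)]).strip()
        try:
            month = int(float(raw_month))
        except ValueError:
            raise RowParseError(idx, f"unparseable month {raw_month!r}") from None
        raw_dx = str(row[df.columns.get_loc(spec.diagnosis_col)]).strip()
        mapped = spec.diagnosis_map.get(raw_dx.upper())
        if mapped is None:
            unknown[raw_dx] += 1
            mapped = "OTHER"
        records.append(
            VisitRecord(
                participant_id=str(row[df.columns.get_loc(spec.id_col)]).strip(),
                month=month,
                diagnosis=Diagnosis(mapped),
            )
        )
    if unknown:
        warnings.warn(
            f"unknown diagnosis labels mapped to OTHER: {dict(unknown)}",
            stacklevel=2,
        )
    records.sort(key=lambda r: (r.participant_id, r.month))
    seen = {}
    for r in records:
        key = (r.participant_id, r.month)
        if key in seen:
            raise FormatError(f"duplicate visit for participant {r.participant_id} at month {r.month}")
        seen[key] = True
    return records


_BOOL_MAP = {"1": True, "1.0": True, "TRUE": True, "YES": True,
             "0": False, "0.0": False, "FALSE": False, "NO": False}


def read_baseline(path, missing_values: Sequence[str] = ("", "NA", "NaN")) -> list[BaselineProfile]:
    """Parse a baseline covariate CSV (one row per participant)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    required = {"participant_id", "age", "sex"}
    if not required <= set(df.columns):
        raise FormatError(f"baseline table lacks mandatory columns {sorted(required - set(df.columns))}")
    miss = set(missing_values)

    def fnum(v):
        v = str(v).strip()
        return None if v in miss else float(v)

    def fbool(v):
        v = str(v).strip()
        if v in miss:
            return None
        try:
            return _BOOL_MAP[v.upper()]
        except KeyError:
            raise FormatError(f"unrecognized boolean value {v!r}") from None

    profiles = []
    for _, row in df.iterrows():
        race = str(row.get("race", "")).strip()
        profiles.append(
            BaselineProfile(
                participant_id=str(row["participant_id"]).strip(),
                age=fnum(row["age"]),
                sex=str(row["sex"]).strip().lower(),
                education=fnum(row.get("education", "")),
                apoe4_carrier=fbool(row.get("apoe4_carrier", "")),
                family_history_dementia=fbool(row.get("family_history_dementia", "")),
                mmse=fnum(row.get("mmse", "")),
                cdr_global=fnum(row.get("cdr_global", "")),
                systolic_bp=fnum(row.get("systolic_bp", "")),
                diastolic_bp=fnum(row.get("diastolic_bp", "")),
                race=None if race in miss else race,
            )
        )
    return profiles


def visits_from_dataframe(df: pd.DataFrame) -> list[VisitRecord]:
    """Build visit records from an in-memory table with the default columns."""
    return [
        VisitRecord(str(r.participant_id), int(r.month), Diagnosis(str(r.diagnosis)))
        for r in df.itertuples(index=False)
    ]


def profiles_from_dataframe(df: pd.DataFrame) -> list[BaselineProfile]:
    """Build baseline profiles from an in-memory table; NaN/None are missing."""

    def miss(v):
        return v is None or (isinstance(v, float) and np.isnan(v)) or (isinstance(v, str) and not v)

    def fnum(v):
        return None if miss(v) else float(v)

    def fbool(v):
        return None if miss(v) else bool(v)

    out = []
    for r in df.itertuples(index=False):
        out.append(
            BaselineProfile(
                participant_id=str(r.participant_id),
                age=float(r.age),
                sex=str(r.sex).lower(),
                education=fnum(getattr(r, "education", None)),
                apoe4_carrier=fbool(getattr(r, "apoe4_carrier", None)),
                family_history_dementia=fbool(getattr(r, "family_history_dementia", None)),
                mmse=fnum(getattr(r, "mmse", None)),
                cdr_global=fnum(getattr(r, "cdr_global", None)),
                systolic_bp=fnum(getattr(r, "systolic_bp", None)),
                diastolic_bp=fnum(getattr(r, "diastolic_bp", None)),
                race=None if miss(getattr(r, "race", None)) else str(r.race),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Outcome derivation


def derive_conversion(visits: Sequence[VisitRecord]) -> SurvivalRecord | Exclusion:
    """Turn one participant's visit stream into an outcome or an exclusion.

    First-hit definition: the event time is the month of the first MCI
    diagnosis (later reversions are ignored).  Participants whose first
    non-CN diagnosis is AD are excluded as direct converters; participants
    with only a baseline visit are excluded as uninformative.  Visits with
    diagnosis OTHER are dropped before the scan.
    """
    if not visits:
        raise InputError("empty visit list")
    pid = visits[0].participant_id
    if any(v.participant_id != pid for v in visits):
        raise InputError("visits from multiple participants passed to derive_conversion")
    ordered = sorted(visits, key=lambda v: v.month)
    if ordered[0].month != 0:
        raise InputError(f"{pid}: no baseline (month 0) visit")
    if ordered[0].diagnosis is not Diagnosis.CN:
        return Exclusion(pid, "baseline-not-cn")
    informative = [v for v in ordered if v.diagnosis is not Diagnosis.OTHER]
    if len(informative) == 1:
        return Exclusion(pid, "baseline-only")
    for v in informative[1:]:
        if v.diagnosis is Diagnosis.MCI:
            return SurvivalRecord(pid, None, time=v.month / 12, event=True)
        if v.diagnosis is Diagnosis.AD:
            return Exclusion(pid, "direct-to-AD")
    last_cn = max(v.month for v in informative if v.diagnosis is Diagnosis.CN)
    return SurvivalRecord(pid, None, time=last_cn / 12, event=False)


def derive_outcomes(
    visits: Iterable[VisitRecord],
) -> tuple[list[SurvivalRecord], list[Exclusion]]:
    """Group a visit stream by participant and derive every outcome.

    Partitions the input: every participant lands in exactly one of the two
    returned lists.
    """
    by_pid: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_pid.setdefault(v.participant_id, []).append(v)
    records, exclusions = [], []
    for pid in sorted(by_pid):
        out = derive_conversion(by_pid[pid])
        (records if isinstance(out, SurvivalRecord) else exclusions).append(out)
    return records, exclusions


# ---------------------------------------------------------------------------
# Inclusion filters and sex stratification


@dataclass
class SexCohorts:
    """Sex-stratified analysis cohorts plus the exclusion audit trail."""

    female: list[SurvivalRecord]
    male: list[SurvivalRecord]
    profiles: dict[str, BaselineProfile]
    exclusions: list[Exclusion]

    def exclusion_counts(self) -> dict[str, int]:
        return dict(Counter(e.reason for e in self.exclusions))

    def to_dataframe(self, sex: str) -> pd.DataFrame:
        recs = getattr(self, sex)
        rows = []
        for r in recs:
            row = {"participant_id": r.participant_id, "sex": r.sex,
                   "time": r.time, "event": int(r.event)}
            row.update(r.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


def apply_inclusion(
    profiles: Iterable[BaselineProfile],
    records: Iterable[SurvivalRecord],
    max_missing_rate: float = 0.10,
    age_range: tuple[float, float] = (61, 90),
    tracked: Sequence[str] = TRACKED_FACTORS,
) -> SexCohorts:
    """Apply age, missing-rate and CDR-validity filters; stratify by sex.

    Retains participants aged within ``age_range`` (both ends inclusive)
    whose per-participant missing rate over ``tracked`` factors does not
    exceed ``max_missing_rate`` and whose global CDR, when present, is one
    of the valid codes.  Survival records without a profile are excluded
    with reason ``no-profile``.  Covariate encodings from the profile are
    attached to each retained record.
    """
    by_pid = {p.participant_id: p for p in profiles}
    cohorts = SexCohorts(female=[], male=[], profiles={}, exclusions=[])
    lo, hi = age_range
    for rec in records:
        prof = by_pid.get(rec.participant_id)
        if prof is None:
            cohorts.exclusions.append(Exclusion(rec.participant_id, "no-profile"))
            continue
        if not lo <= prof.age <= hi:
            cohorts.exclusions.append(Exclusion(rec.participant_id, "age-out-of-range"))
            continue
        if prof.missing_rate(tracked) > max_missing_rate:
            cohorts.exclusions.append(Exclusion(rec.participant_id, "missing-rate"))
            continue
        if prof.cdr_global is not None and prof.cdr_global not in ALLOWED_CDR:
            cohorts.exclusions.append(Exclusion(rec.participant_id, "abnormal-cdr"))
            continue
        out = replace(rec, sex=prof.sex, covariates=prof.covariates())
        if prof.sex == "female":
            cohorts.female.append(out)
        elif prof.sex == "male":
            cohorts.male.append(out)
        else:
            cohorts.exclusions.append(Exclusion(rec.participant_id, "unknown-sex"))
            continue
        cohorts.profiles[rec.participant_id] = prof
    for sex in ("female", "male"):
        if not getattr(cohorts, sex):
            warnings.warn(f"inclusion filters left an empty {sex} cohort", stacklevel=2)
    return cohorts


# ---------------------------------------------------------------------------
# Covariate balance


def standardized_difference(group1, group2, kind: str = "continuous") -> float:
    """Signed standardized difference between two groups.

    Continuous: d = (x̄₁ − x̄₂) / √((s₁² + s₂²)/2) with sample variances.
    Categorical (binary): d = (p₁ − p₂) / √((p₁(1−p₁) + p₂(1−p₂))/2);
    the inputs may be 0/1 arrays or scalar proportions.
    |d| > 0.1 is the conventional imbalance flag.
    """
    if kind == "continuous":
        a = np.asarray(group1, dtype=float)
        b = np.asarray(group2, dtype=float)
        if a.size == 0 or b.size == 0:
            raise InputError("both groups must be non-empty")
        m1, m2 = a.mean(), b.mean()
        v1 = a.var(ddof=1) if a.size > 1 else 0.0
        v2 = b.var(ddof=1) if b.size > 1 else 0.0
        denom = np.sqrt((v1 + v2) / 2)
    elif kind == "categorical":
        p1 = float(np.mean(group1))
        p2 = float(np.mean(group2))
        if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
            raise InputError("proportions must lie in [0, 1]")
        m1, m2 = p1, p2
        denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
    else:
        raise InputError(f"unknown kind {kind!r}")
    if denom == 0:
        if m1 == m2:
            return 0.0
        raise DegenerateInputError(
            "standardized difference undefined: zero pooled variance with unequal means"
        )
    return float((m1 - m2) / denom)


_CONTINUOUS_FACTORS = {"age", "education", "mmse", "cdr_global", "systolic_bp", "diastolic_bp"}
_BINARY_FACTORS = {"apoe4_carrier", "family_history_dementia"}


def balance_table(
    profiles1: Sequence[BaselineProfile],
    profiles2: Sequence[BaselineProfile],
    factors: Sequence[str] = TRACKED_FACTORS,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Standardized-difference balance table between two groups of profiles.

    Multi-level factors (race) report the level with the largest absolute
    indicator difference.  Missing values are dropped per factor.
    """

    def values(profiles, name):
        return [getattr(p, name) for p in profiles if getattr(p, name) is not None]

    rows = []
    for name in factors:
        v1, v2 = values(profiles1, name), values(profiles2, name)
        if not v1 or not v2:
            rows.append({"factor": name, "d": np.nan, "imbalanced": False})
            continue
        if name in _CONTINUOUS_FACTORS:
            d = standardized_difference(v1, v2, "continuous")
        elif name in _BINARY_FACTORS:
            d = standardized_difference([float(x) for x in v1], [float(x) for x in v2], "categorical")
        else:  # multi-level categorical
            levels = sorted(set(v1) | set(v2))
            best = 0.0
            for lev in levels:
                d_lev = standardized_difference(
                    [float(x == lev) for x in v1], [float(x == lev) for x in v2], "categorical"
                )
                if abs(d_lev) > abs(best):
                    best = d_lev
            d = best
        rows.append({"factor": name, "d": d, "imbalanced": bool(abs(d) > threshold)})
    return pd.DataFrame(rows)
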