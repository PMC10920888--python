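"""Hospital-stay ingestion, cohort wash-out and diagnosis events.

The raw unit is one in-patient stay: pseudonymous patient id, sex, age at
admission in 5-year bands, admission/release dates, release type
(discharge/transfer/death) and an ordered diagnosis list (primary first,
secondaries after) of three-character ICD-10 codes.

Downstream analysis works on *diagnosis events*: one row per distinct
(patient, code, ten-year age group, calendar year).  Primary and secondary
diagnoses are treated identically.  A wash-out period (default 1997–2002)
removes every patient hospitalized before the observation window so the
cohort is "healthy" at baseline and coded under a single ICD revision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from ._icd import (
    CODE_RANGE,
    SENTINEL,
    age_band_to_group,
    in_code_range,
    is_valid_code,
)

SEXES = ("male", "female")
RELEASE_TYPES = ("discharge", "transfer", "death")
_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}

#: canonical event-table columns
EVENT_COLUMNS = ("patient_id", "sex", "code", "age_group", "year")


@dataclass(frozen=True)
class HospitalStay:
    """One validated in-patient stay."""

    patient_id: str
    sex: str
    age_band: int
    admission_date: date
    release_date: date
    release_type: str
    diagnoses: tuple[str, ...]  # primary first

    def __post_init__(self):
        if self.release_date < self.admission_date:
            raise ValueError("release before admission")
        if self.age_band % 5 or not (0 <= self.age_band <= 95):
            raise ValueError(f"bad age band {self.age_band}")
        if self.sex not in SEXES:
            raise ValueError(f"bad sex {self.sex!r}")
        if self.release_type not in RELEASE_TYPES:
            raise ValueError(f"bad release type {self.release_type!r}")
        if not self.diagnoses:
            raise ValueError("empty diagnosis list")
        for c in self.diagnoses:
            if not is_valid_code(c):
                raise ValueError(f"malformed code {c!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort definition: wash-out + observation windows and code range."""

    washout_years: tuple[int, int] = (1997, 2002)
    observation_years: tuple[int, int] = (2003, 2014)
    code_range: tuple[str, str] = CODE_RANGE
    sex_split: bool = True
    #: emit the sentinel code for hospitalizations with no in-range
    #: diagnosis ("emit") or drop them ("drop")
    sentinel_policy: str = "emit"

    def __post_init__(self):
        if self.washout_years[1] >= self.observation_years[0]:
            raise ValueError("wash-out must precede observation window")
        if self.sentinel_policy not in ("emit", "drop"):
            raise ValueError("sentinel_policy must be 'emit' or 'drop'")


DEFAULT_SCHEMA = {
    "patient_id": "patient_id",
    "sex": "sex",
    "age": "age",
    "admission_date": "admission_date",
    "release_date": "release_date",
    "release_type": "release_type",
    "diagnoses": "diagnoses",
}


def _parse_row(row, schema) -> HospitalStay:
    def get(key):
        col = schema.get(key, key)
        return row[col]

    sex = _SEX_ALIASES.get(str(get("sex")).strip().lower())
    if sex is None:
        raise ValueError(f"unrecognized sex {get('sex')!r}")
    admission = date.fromisoformat(str(get("admission_date")))
    release = date.fromisoformat(str(get("release_date")))
    diag_col = schema.get("diagnoses", "diagnoses")
    if diag_col in row.index and not pd.isna(row[diag_col]):
        codes = [c.strip() for c in str(row[diag_col]).split(";") if c.strip()]
    else:  # diag1..diagN layout
        codes = []
        for col in row.index:
            if col.startswith("diag") and col[4:].isdigit() and not pd.isna(row[col]):
                codes.append((int(col[4:]), str(row[col]).strip()))
        codes = [c for _, c in sorted(codes)]
    return HospitalStay(
        patient_id=str(get("patient_id")),
        sex=sex,
        age_band=int(get("age")),
        admission_date=admission,
        release_date=release,
        release_type=str(get("release_type")).strip().lower(),
        diagnoses=tuple(codes),
    )


def read_stays(path, schema=None):
    """Read a stays CSV, validating every row.

    Returns ``(stays, rejects)`` where ``rejects`` is a DataFrame with the
    offending row index and a human-readable reason; invalid rows are
    reported, never silently dropped.

    The CSV needs columns patient_id, sex, age, admission_date,
    release_date, release_type and either a semicolon-joined ``diagnoses``
    column or ``diag1..diagN`` columns.  ``schema`` remaps logical to
    actual column names.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str)
    required = [schema[k] for k in ("patient_id", "sex", "age", "admission_date",
                                    "release_date", "release_type")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    has_diag = schema["diagnoses"] in df.columns or any(
        c.startswith("diag") and c[4:].isdigit() for c in df.columns)
    if not has_diag:
        raise ValueError("no diagnosis column(s) found")

    stays, rejects = [], []
    for idx, row in df.iterrows():
        try:
            stays.append(_parse_row(row, schema))
        except (ValueError, KeyError, TypeError) as exc:
            rejects.append({"row": idx, "reason": str(exc)})
    return stays, pd.DataFrame(rejects, columns=["row", "reason"])


def write_stays(stays, path):
    """Write stays in the canonical CSV dialect (semicolon-joined codes)."""
    rows = [
        {
            "patient_id": s.patient_id,
            "sex": s.sex,
            "age": s.age_band,
            "admission_date": s.admission_date.isoformat(),
            "release_date": s.release_date.isoformat(),
            "release_type": s.release_type,
            "diagnoses": ";".join(s.diagnoses),
        }
        for s in stays
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def apply_washout(stays, cfg: CohortConfig = CohortConfig()):
    """Drop every patient hospitalized during the wash-out years.

    Returns ``(cohort_ids, filtered_stays)``: the retained patient-id set
    and their stays restricted to the observation window.  Only the
    admission year is used for windowing.
    """
    w_lo, w_hi = cfg.washout_years
    o_lo, o_hi = cfg.observation_years
    washed = {s.patient_id for s in stays if w_lo <= s.admission_date.year <= w_hi}
    cohort = frozenset({s.patient_id for s in stays} - washed)
    kept = [
        s for s in stays
        if s.patient_id in cohort and o_lo <= s.admission_date.year <= o_hi
    ]
    if not kept:
        warnings.warn("wash-out removed every stay", stacklevel=2)
    return cohort, kept


def to_events(stays, cfg: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Collapse cohort stays into distinct diagnosis events.

    One row per (patient, code, age_group, year); primary and secondary
    codes are treated identically; codes outside the analysis range are
    dropped; stays at age 80+ are outside the eight-layer universe and
    yield nothing.  A hospitalization whose codes are all out of range
    yields one sentinel event (policy ``emit``) so the patient still
    counts as hospitalized in that layer.
    """
    rows = []
    for s in stays:
        g = age_band_to_group(s.age_band)
        if g is None:
            continue
        year = s.admission_date.year
        kept = {c for c in s.diagnoses if in_code_range(c, cfg.code_range)}
        if not kept and cfg.sentinel_policy == "emit":
            kept = {SENTINEL}
        for code in sorted(kept):
            rows.append((s.patient_id, s.sex, code, g, year))
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events = events.drop_duplicates(ignore_index=True)
    return events.sort_values(list(EVENT_COLUMNS), ignore_index=True)


def stays_frame(stays) -> pd.DataFrame:
    """Per-stay utilization table used by the outcomes stage."""
    rows = [
        {
            "patient_id": s.patient_id,
            "sex": s.sex,
            "age_group": age_band_to_group(s.age_band),
            "year": s.admission_date.year,
            "days": (s.release_date - s.admission_date).days,
            "death": s.release_type == "death",
        }
        for s in stays
    ]
    df = pd.DataFrame(
        rows, columns=["patient_id", "sex", "age_group", "year", "days", "death"]
    )
    return df[df["age_group"].notna()].reset_index(drop=True)
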