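"""Encounter-level EHR data model.

One inpatient hospitalization ("admission") is the unit of analysis; every
clinical record (lab, culture, flowsheet observation, medication event,
procedure) links to an admission by ``encounter_id`` or, for sources that are
audited with a look-back window reaching before the index admission, to the
patient by ``patient_id``.

Timestamps are either :class:`datetime.datetime` (raw extracts) or floats in
fractional days (de-identified cohorts, where all dates are offsets from the
patient's first recorded event). All window arithmetic goes through
:func:`to_days` so both representations behave identically.
"""
from __future__ import annotations

import hashlib
import logging
from collections import defaultdict
from dataclasses import dataclass, field, fields, replace
from datetime import datetime
from pathlib import Path
from typing import Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

TimeLike = Union[datetime, float]

SEXES = ("male", "female")
RACE_ETHNICITIES = (
    "Asian/Pacific Islander",
    "Black",
    "Caucasian-Hispanic",
    "Caucasian-Non-Hispanic",
    "Other-Hispanic",
    "Other-Non-Hispanic",
)

_EPOCH = datetime(1970, 1, 1)
SECONDS_PER_DAY = 86400.0


def to_days(t: TimeLike) -> float:
    """Convert a timestamp to fractional days on a common linear scale."""
    if isinstance(t, datetime):
        if t.tzinfo is not None:
            t = t.replace(tzinfo=None)
        return (t - _EPOCH).total_seconds() / SECONDS_PER_DAY
    return float(t)


def normalize_icd(code: str) -> str:
    return code.strip().upper()


class SchemaError(ValueError):
    """A cohort file is missing, lacks a required column, or has a bad row."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass
class AdmissionRecord:
    encounter_id: str
    patient_id: str
    admit_time: TimeLike
    discharge_time: TimeLike
    died_inpatient: bool
    raw_financial_class: str
    sex: str
    race_ethnicity: str
    age_years: float
    billed_icd_codes: list[str] = field(default_factory=list)
    billed_drg_code: Optional[str] = None


@dataclass
class LabResult:
    collected_time: TimeLike
    analyte: str
    encounter_id: Optional[str] = None
    patient_id: Optional[str] = None
    numeric_value: Optional[float] = None
    abnormal_flag: Optional[str] = None


@dataclass
class CultureResult:
    encounter_id: str
    collected_time: TimeLike
    specimen: str  # blood | urine
    positive: bool
    colony_count: Optional[float] = None


@dataclass
class FlowsheetObservation:
    observed_time: TimeLike
    measure: str
    value: Union[float, str]
    encounter_id: Optional[str] = None
    patient_id: Optional[str] = None


@dataclass
class MedicationEvent:
    event_time: TimeLike
    drug: str
    event_kind: str  # order_active | administration
    encounter_id: Optional[str] = None
    patient_id: Optional[str] = None


@dataclass
class ProcedureEvent:
    event_time: TimeLike
    kind: str  # surgery_case | coronary_stent | transplant_surgery
    encounter_id: Optional[str] = None
    patient_id: Optional[str] = None
    cpt_codes: list[str] = field(default_factory=list)


CHILD_TABLES = ("labs", "cultures", "flowsheets", "medications", "procedures")

TIME_FIELD = {
    "labs": "collected_time",
    "cultures": "collected_time",
    "flowsheets": "observed_time",
    "medications": "event_time",
    "procedures": "event_time",
}


@dataclass
class Cohort:
    """In-memory cohort: one admissions table plus five clinical-source tables."""

    admissions: list[AdmissionRecord] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    cultures: list[CultureResult] = field(default_factory=list)
    flowsheets: list[FlowsheetObservation] = field(default_factory=list)
    medications: list[MedicationEvent] = field(default_factory=list)
    procedures: list[ProcedureEvent] = field(default_factory=list)
    _cache: Optional[dict] = field(default=None, repr=False, compare=False)

    def records(self, table: str) -> list:
        return getattr(self, table)

    def reindex(self) -> None:
        """Drop cached linkage indexes (call after mutating record lists)."""
        self._cache = None

    def _index(self) -> dict:
        if self._cache is None:
            enc_to_pat = {a.encounter_id: a.patient_id for a in self.admissions}
            by_enc: dict = {t: defaultdict(list) for t in CHILD_TABLES}
            by_pat: dict = {t: defaultdict(list) for t in CHILD_TABLES}
            for t in CHILD_TABLES:
                for rec in self.records(t):
                    eid = getattr(rec, "encounter_id", None)
                    pid = getattr(rec, "patient_id", None)
                    if eid:
                        by_enc[t][eid].append(rec)
                    owner = pid or enc_to_pat.get(eid or "")
                    if owner:
                        by_pat[t][owner].append(rec)
            self._cache = {
                "by_enc": by_enc,
                "by_pat": by_pat,
                "adm": {a.encounter_id: a for a in self.admissions},
            }
        return self._cache

    def admission(self, encounter_id: str) -> Optional[AdmissionRecord]:
        return self._index()["adm"].get(encounter_id)

    def encounter_records(self, table: str, encounter_id: str) -> list:
        """Records of ``table`` linked to the encounter directly."""
        return self._index()["by_enc"][table].get(encounter_id, [])

    def patient_records(self, table: str, patient_id: str) -> list:
        """Records of ``table`` owned by the patient (directly or via any encounter)."""
        return self._index()["by_pat"][table].get(patient_id, [])


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

TABLE_FILES = {
    "admissions": "admissions.csv",
    "labs": "labs.csv",
    "cultures": "cultures.csv",
    "flowsheets": "flowsheets.csv",
    "medications": "medications.csv",
    "procedures": "procedures.csv",
}

TABLE_COLUMNS = {
    "admissions": [
        "encounter_id", "patient_id", "admit_time", "discharge_time",
        "died_inpatient", "raw_financial_class", "sex", "race_ethnicity",
        "age_years", "billed_icd_codes", "billed_drg_code",
    ],
    "labs": ["encounter_id", "patient_id", "collected_time", "analyte",
             "numeric_value", "abnormal_flag"],
    "cultures": ["encounter_id", "collected_time", "specimen", "positive",
                 "colony_count"],
    "flowsheets": ["encounter_id", "patient_id", "observed_time", "measure",
                   "value"],
    "medications": ["encounter_id", "patient_id", "event_time", "drug",
                    "event_kind"],
    "procedures": ["encounter_id", "patient_id", "event_time", "kind",
                   "cpt_codes"],
}

LIST_SEP = ";"


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, datetime):
        return value.isoformat()
    if isinstance(value, list):
        return LIST_SEP.join(str(v) for v in value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_time(text: str, *, where: str):
    try:
        return float(text)
    except ValueError:
        pass
    try:
        return datetime.fromisoformat(text)
    except ValueError:
        raise SchemaError(f"unparseable timestamp {text!r} at {where}") from None


def _parse_opt_float(text: str) -> Optional[float]:
    return float(text) if text != "" else None


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def _parse_value(text: str) -> Union[float, str]:
    try:
        return float(text)
    except ValueError:
        return text


def write_cohort(cohort: Cohort, directory: Union[str, Path]) -> dict[str, Path]:
    """Write one CSV per table; output is losslessly re-readable by read_cohort."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for table, filename in TABLE_FILES.items():
        cols = TABLE_COLUMNS[table]
        rows = [
            {c: _fmt(getattr(rec, c, None)) for c in cols}
            for rec in cohort.records(table)
        ]
        frame = pd.DataFrame(rows, columns=cols)
        path = directory / filename
        frame.to_csv(path, index=False, lineterminator="\n")
        written[table] = path
    return written


def _row_records(table: str, frame: pd.DataFrame, filename: str) -> list:
    out = []
    tf = TIME_FIELD.get(table)
    for i, row in enumerate(frame.to_dict("records")):
        where = f"{filename} row {i}"
        try:
            if table == "admissions":
                rec: object = AdmissionRecord(
                    encounter_id=row["encounter_id"],
                    patient_id=row["patient_id"],
                    admit_time=_parse_time(row["admit_time"], where=where),
                    discharge_time=_parse_time(row["discharge_time"], where=where),
                    died_inpatient=_parse_bool(row["died_inpatient"]),
                    raw_financial_class=row["raw_financial_class"],
                    sex=row["sex"],
                    race_ethnicity=row["race_ethnicity"],
                    age_years=float(row["age_years"]),
                    billed_icd_codes=[c for c in row["billed_icd_codes"].split(LIST_SEP) if c],
                    billed_drg_code=row["billed_drg_code"] or None,
                )
            elif table == "labs":
                rec = LabResult(
                    encounter_id=row["encounter_id"] or None,
                    patient_id=row["patient_id"] or None,
                    collected_time=_parse_time(row[tf], where=where),
                    analyte=row["analyte"],
                    numeric_value=_parse_opt_float(row["numeric_value"]),
                    abnormal_flag=row["abnormal_flag"] or None,
                )
            elif table == "cultures":
                rec = CultureResult(
                    encounter_id=row["encounter_id"],
                    collected_time=_parse_time(row[tf], where=where),
                    specimen=row["specimen"],
                    positive=_parse_bool(row["positive"]),
                    colony_count=_parse_opt_float(row["colony_count"]),
                )
            elif table == "flowsheets":
                rec = FlowsheetObservation(
                    encounter_id=row["encounter_id"] or None,
                    patient_id=row["patient_id"] or None,
                    observed_time=_parse_time(row[tf], where=where),
                    measure=row["measure"],
                    value=_parse_value(row["value"]),
                )
            elif table == "medications":
                rec = MedicationEvent(
                    encounter_id=row["encounter_id"] or None,
                    patient_id=row["patient_id"] or None,
                    event_time=_parse_time(row[tf], where=where),
                    drug=row["drug"],
                    event_kind=row["event_kind"],
                )
            else:
                rec = ProcedureEvent(
                    encounter_id=row["encounter_id"] or None,
                    patient_id=row["patient_id"] or None,
                    event_time=_parse_time(row[tf], where=where),
                    kind=row["kind"],
                    cpt_codes=[c for c in row["cpt_codes"].split(LIST_SEP) if c],
                )
        except SchemaError:
            raise
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"bad value at {where}: {exc}") from exc
        out.append(rec)
    return out


def read_cohort(directory: Union[str, Path],
                schema_config: Optional[dict] = None) -> Cohort:
    """Read a cohort from one delimited file per table.

    ``schema_config`` maps, per table, a logical column name to the column
    name actually present in the file, so foreign extracts can be adapted
    without code changes:  ``{"admissions": {"encounter_id": "CSN"}}``.
    """
    directory = Path(directory)
    schema_config = schema_config or {}
    tables: dict[str, list] = {}
    for table, filename in TABLE_FILES.items():
        path = directory / filename
        if not path.exists():
            raise SchemaError(f"missing required file {filename}")
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        rename = {actual: logical
                  for logical, actual in schema_config.get(table, {}).items()}
        frame = frame.rename(columns=rename)
        required = TABLE_COLUMNS[table]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(
                f"file {filename} is missing required column(s) {missing}")
        extra = [c for c in frame.columns if c not in required]
        if extra:
            logger.warning("ignoring unknown columns %s in %s", extra, filename)
            frame = frame[required]
        tables[table] = _row_records(table, frame, filename)
    return Cohort(**tables)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    table: str
    locator: str
    message: str


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check structural invariants; returns every violation, never raises."""
    out: list[Violation] = []
    seen_enc: set[str] = set()
    patients: set[str] = set()
    for a in cohort.admissions:
        loc = f"encounter {a.encounter_id}"
        if a.encounter_id in seen_enc:
            out.append(Violation("admissions", loc, "duplicate encounter_id"))
        seen_enc.add(a.encounter_id)
        patients.add(a.patient_id)
        if to_days(a.admit_time) > to_days(a.discharge_time):
            out.append(Violation("admissions", loc, "discharge before admit"))
        if a.age_years < 0:
            out.append(Violation("admissions", loc, "negative age"))
        codes = [normalize_icd(c) for c in a.billed_icd_codes]
        if len(codes) != len(set(codes)):
            out.append(Violation("admissions", loc,
                                 "duplicate billed ICD codes after normalization"))

    for table in CHILD_TABLES:
        for i, rec in enumerate(cohort.records(table)):
            loc = f"row {i}"
            eid = getattr(rec, "encounter_id", None)
            pid = getattr(rec, "patient_id", None)
            linked = (eid in seen_enc) or (pid in patients)
            if not linked:
                out.append(Violation(table, loc,
                                     "dangling reference: no matching admission or patient"))
            if table == "labs":
                if rec.numeric_value is None and rec.abnormal_flag is None:
                    out.append(Violation(table, loc,
                                         "lab has neither numeric_value nor abnormal_flag"))
            elif table == "cultures":
                if rec.colony_count is not None:
                    if rec.specimen != "urine":
                        out.append(Violation(table, loc,
                                             "colony_count on non-urine specimen"))
                    elif rec.colony_count < 0:
                        out.append(Violation(table, loc, "negative colony_count"))
            elif table == "flowsheets":
                v = rec.value
                if rec.measure == "GCS_total" and isinstance(v, float) and not 3 <= v <= 15:
                    out.append(Violation(table, loc, "GCS out of [3,15]"))
                if rec.measure == "BMI" and isinstance(v, float) and v <= 0:
                    out.append(Violation(table, loc, "non-positive BMI"))
                if rec.measure == "ejection_fraction" and isinstance(v, float) \
                        and not 0 < v <= 100:
                    out.append(Violation(table, loc, "ejection fraction outside (0,100]"))
            elif table == "medications":
                if not rec.drug:
                    out.append(Violation(table, loc, "empty drug name"))
    return out


# ---------------------------------------------------------------------------
# De-identification
# ---------------------------------------------------------------------------

def _hash_id(salt: str, raw: str) -> str:
    return hashlib.sha256(f"{salt}:{raw}".encode()).hexdigest()[:16]


def deidentify(cohort: Cohort, salt: str) -> Cohort:
    """Replace identifiers with salted one-way hashes and dates with day offsets.

    Every patient/encounter id becomes a truncated SHA-256 of ``salt:id`` —
    the hash is keyed per patient because the id participates in the digest.
    Every timestamp becomes the fractional-day offset from that patient's
    earliest recorded event, so orderings and all inter-event intervals are
    preserved exactly while absolute dates disappear.
    """
    if not salt:
        raise ValueError("salt must be non-empty")

    enc_to_pat = {a.encounter_id: a.patient_id for a in cohort.admissions}

    first_event: dict[str, float] = {}

    def note(pid: Optional[str], t: TimeLike) -> None:
        if pid is None:
            return
        d = to_days(t)
        if pid not in first_event or d < first_event[pid]:
            first_event[pid] = d

    for a in cohort.admissions:
        note(a.patient_id, a.admit_time)
    for table in CHILD_TABLES:
        tf = TIME_FIELD[table]
        for rec in cohort.records(table):
            pid = getattr(rec, "patient_id", None) or enc_to_pat.get(
                getattr(rec, "encounter_id", None) or "")
            note(pid, getattr(rec, tf))

    def offset(pid: Optional[str], t: TimeLike) -> float:
        base = first_event.get(pid or "", 0.0)
        return to_days(t) - base

    new = Cohort()
    for a in cohort.admissions:
        new.admissions.append(replace(
            a,
            encounter_id=_hash_id(salt, a.encounter_id),
            patient_id=_hash_id(salt, a.patient_id),
            admit_time=offset(a.patient_id, a.admit_time),
            discharge_time=offset(a.patient_id, a.discharge_time),
        ))
    for table in CHILD_TABLES:
        tf = TIME_FIELD[table]
        for rec in cohort.records(table):
            eid = getattr(rec, "encounter_id", None)
            pid = getattr(rec, "patient_id", None)
            owner = pid or enc_to_pat.get(eid or "")
            changes = {tf: offset(owner, getattr(rec, tf))}
            if eid is not None:
                changes["encounter_id"] = _hash_id(salt, eid)
            if pid is not None and "patient_id" in {f.name for f in fields(rec)}:
                changes["patient_id"] = _hash_id(salt, pid)
            new.records(table).append(replace(rec, **changes))
    return new
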