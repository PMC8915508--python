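"""Admission-record data model, CSV I/O and cohort inclusion criteria.

One :class:`AdmissionRecord` describes a single hospitalization of an elderly
patient: demographics, hospital attributes, admission/discharge dates and up
to 16 three-character ICD-10 diagnoses, each carrying a point-of-admission
(PoA) flag.  The principal diagnosis is always position 0.

The on-disk dialect is a UTF-8 CSV with a header row, ISO-8601 dates, one row
per admission, diagnosis columns ``diag_01..diag_16`` paired with
``poa_01..poa_16``, and the empty string for missing values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

import pandas as pd

MAX_DIAGNOSES = 16
_ICD3 = re.compile(r"^[A-Z][0-9]{2}$")

#: CSV columns other than the diagnosis/PoA pairs, in file order.
MANDATORY_COLUMNS = [
    "record_id", "patient_id", "sex", "age", "ethnic_group",
    "admission_date", "discharge_date", "los",
    "hospital_id", "hospital_level", "hospital_grade", "hospital_affiliation",
    "hospital_address_code", "patient_address_code",
    "admission_status", "admission_source", "job", "marital_status",
]


class SchemaError(ValueError):
    """The file is missing a mandatory column."""


class RecordValidationError(ValueError):
    """A row violates the record invariants; carries the offending row numbers."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class AdmissionRecord:
    """A single hospitalization with diagnoses and PoA flags."""

    record_id: str
    patient_id: str
    sex: str                      # "male" | "female"
    age: int                      # integer years at admission
    ethnic_group: str             # "han" | "minority"
    admission_date: date
    discharge_date: date
    los: int                      # whole days, discharge − admission
    hospital_id: str
    hospital_level: int           # ordinal quality level (1–3)
    hospital_grade: int           # ordinal quality grade within level (1–3)
    hospital_affiliation: int
    hospital_address_code: int
    patient_address_code: int
    admission_status: int         # 1 danger, 2 urgent, 3 general
    admission_source: int         # 1..4
    job: int                      # 1..13
    marital_status: int           # 1..4
    diagnoses: tuple[tuple[str, bool], ...] = field(default_factory=tuple)
    alive: bool = True            # criterion (2); absent from the file schema

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.los != (self.discharge_date - self.admission_date).days:
            problems.append(
                f"record {self.record_id}: los={self.los} does not equal the "
                f"admission→discharge day difference"
            )
        if self.los < 0:
            problems.append(f"record {self.record_id}: negative los")
        if not 1 <= len(self.diagnoses) <= MAX_DIAGNOSES:
            problems.append(
                f"record {self.record_id}: {len(self.diagnoses)} diagnoses "
                f"(must be 1..{MAX_DIAGNOSES})"
            )
        for code, flag in self.diagnoses:
            if not _ICD3.match(code):
                problems.append(
                    f"record {self.record_id}: malformed ICD-10 code {code!r}"
                )
            if not isinstance(flag, bool):
                problems.append(f"record {self.record_id}: non-boolean PoA flag")
        if self.sex not in ("male", "female"):
            problems.append(f"record {self.record_id}: sex {self.sex!r}")
        return problems

    @property
    def principal_diagnosis(self) -> str:
        return self.diagnoses[0][0]

    def poa_codes(self) -> set[str]:
        """Diagnosis codes flagged at the point of admission."""
        return {c for c, f in self.diagnoses if f}

    def all_codes(self) -> set[str]:
        return {c for c, _ in self.diagnoses}


@dataclass(frozen=True)
class ChronicDiseaseCatalog:
    """Set of 3-character ICD-10 codes regarded as chronic diseases.

    Membership is an exact string match at the 3-character level.  The
    catalog is an input: the published chronic-disease criteria are not
    bundled, and synthetic cohorts carry their own catalog.
    """

    codes: frozenset[str]
    source_label: str = "user-supplied"

    def __post_init__(self):
        if not self.codes:
            raise ValueError("chronic-disease catalog must be non-empty")
        bad = sorted(c for c in self.codes if not _ICD3.match(c))
        if bad:
            raise ValueError(f"malformed catalog codes: {bad}")

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    @classmethod
    def from_codes(cls, codes: Iterable[str], source_label: str = "user-supplied"):
        return cls(frozenset(codes), source_label)


@dataclass(frozen=True)
class InclusionConfig:
    """Cohort inclusion criteria applied in the listed order.

    1. LOS present and non-negative;
    2. alive over the study period;
    3. admission date within ``date_range`` and age ≥ ``min_age``;
    4. LOS ≤ the ``los_quantile`` cutoff (nearest-rank, recomputed from the
       records surviving 1–3 unless ``los_cutoff_days`` pins it);
    5. at least one chronic diagnosis flagged at the PoA.
    """

    min_age: int = 65
    los_quantile: float = 0.99
    date_range: tuple[date, date] | None = None
    require_chronic_at_poa: bool = True
    los_cutoff_days: int | None = None

    def __post_init__(self):
        if not 0 < self.los_quantile < 1:
            raise ValueError("los_quantile must lie in (0, 1)")
        if self.date_range is not None and self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start is after end")


def compute_los_quantile_cutoff(records: Sequence[AdmissionRecord], q: float) -> int:
    """Nearest-rank q-quantile of the LOS values, as integer days.

    With n sorted values the nearest-rank quantile is the value at rank
    ``ceil(q*n)`` (1-based).
    """
    if not records:
        raise ValueError("cannot compute a quantile of zero records")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    los = sorted(r.los for r in records)
    rank = math.ceil(q * len(los))
    return int(los[rank - 1])


def apply_inclusion_criteria(
    records: Sequence[AdmissionRecord],
    catalog: ChronicDiseaseCatalog,
    cfg: InclusionConfig,
) -> tuple[list[AdmissionRecord], dict[str, int]]:
    """Filter records by the study criteria; return (kept, per-criterion tally).

    Criteria are applied in order, so each removed record is attributed to
    the first criterion it violates.  ``|input| = |kept| + Σ tally``.
    """
    tally = {
        "null_or_negative_los": 0,
        "not_alive": 0,
        "out_of_range_date": 0,
        "age_below_minimum": 0,
        "los_above_cutoff": 0,
        "no_chronic_poa_diagnosis": 0,
    }

    def pre_cutoff_ok(r: AdmissionRecord) -> bool:
        if r.los is None or r.los < 0:
            return False
        if not r.alive:
            return False
        if cfg.date_range is not None and not (
            cfg.date_range[0] <= r.admission_date <= cfg.date_range[1]
        ):
            return False
        return r.age >= cfg.min_age

    if cfg.los_cutoff_days is not None:
        cutoff = cfg.los_cutoff_days
    else:
        survivors = [r for r in records if pre_cutoff_ok(r)]
        cutoff = (
            compute_los_quantile_cutoff(survivors, cfg.los_quantile)
            if survivors
            else 0
        )

    kept = []
    for r in records:
        if r.los is None or r.los < 0:
            tally["null_or_negative_los"] += 1
        elif not r.alive:
            tally["not_alive"] += 1
        elif cfg.date_range is not None and not (
            cfg.date_range[0] <= r.admission_date <= cfg.date_range[1]
        ):
            tally["out_of_range_date"] += 1
        elif r.age < cfg.min_age:
            tally["age_below_minimum"] += 1
        elif r.los > cutoff:
            tally["los_above_cutoff"] += 1
        elif cfg.require_chronic_at_poa and not (r.poa_codes() & catalog.codes):
            tally["no_chronic_poa_diagnosis"] += 1
        else:
            kept.append(r)
    return kept, tally


# ---------------------------------------------------------------------------
# CSV dialect

def _record_to_row(r: AdmissionRecord) -> dict:
    row = {
        "record_id": r.record_id,
        "patient_id": r.patient_id,
        "sex": r.sex,
        "age": r.age,
        "ethnic_group": r.ethnic_group,
        "admission_date": r.admission_date.isoformat(),
        "discharge_date": r.discharge_date.isoformat(),
        "los": r.los,
        "hospital_id": r.hospital_id,
        "hospital_level": r.hospital_level,
        "hospital_grade": r.hospital_grade,
        "hospital_affiliation": r.hospital_affiliation,
        "hospital_address_code": r.hospital_address_code,
        "patient_address_code": r.patient_address_code,
        "admission_status": r.admission_status,
        "admission_source": r.admission_source,
        "job": r.job,
        "marital_status": r.marital_status,
    }
    for i in range(MAX_DIAGNOSES):
        code, flag = ("", "") if i >= len(r.diagnoses) else (
            r.diagnoses[i][0], int(r.diagnoses[i][1])
        )
        row[f"diag_{i + 1:02d}"] = code
        row[f"poa_{i + 1:02d}"] = flag
    return row


def write_records(records: Sequence[AdmissionRecord], path) -> None:
    """Serialize records to the CSV dialect (header-only file when empty)."""
    cols = MANDATORY_COLUMNS + [
        f"{p}_{i + 1:02d}" for i in range(MAX_DIAGNOSES) for p in ("diag", "poa")
    ]
    df = pd.DataFrame([_record_to_row(r) for r in records], columns=cols)
    df.to_csv(path, index=False)


def read_records(path, strict: bool = True) -> list[AdmissionRecord]:
    """Parse the CSV dialect into records.

    Malformed rows are reported with their (1-based, header-exclusive) row
    numbers; ``strict=False`` downgrades row-level problems from an exception
    to silently dropping the offending rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    records, problems = [], []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            diagnoses = []
            for i in range(MAX_DIAGNOSES):
                code = row.get(f"diag_{i + 1:02d}", "")
                if code == "":
                    continue
                flag_raw = row.get(f"poa_{i + 1:02d}", "")
                diagnoses.append((code, flag_raw in ("1", "True", "true")))
            rec = AdmissionRecord(
                record_id=row["record_id"],
                patient_id=row["patient_id"],
                sex=row["sex"],
                age=int(row["age"]),
                ethnic_group=row["ethnic_group"],
                admission_date=date.fromisoformat(row["admission_date"]),
                discharge_date=date.fromisoformat(row["discharge_date"]),
                los=int(row["los"]),
                hospital_id=row["hospital_id"],
                hospital_level=int(row["hospital_level"]),
                hospital_grade=int(row["hospital_grade"]),
                hospital_affiliation=int(row["hospital_affiliation"]),
                hospital_address_code=int(row["hospital_address_code"]),
                patient_address_code=int(row["patient_address_code"]),
                admission_status=int(row["admission_status"]),
                admission_source=int(row["admission_source"]),
                job=int(row["job"]),
                marital_status=int(row["marital_status"]),
                diagnoses=tuple(diagnoses),
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"row {idx}: {exc}")
            continue
        row_problems = rec.validate()
        # A negative LOS is a *flagged* record, not a parse failure: it must
        # survive reading so the inclusion filter can tally it.
        hard = [p for p in row_problems if "negative los" not in p]
        if hard:
            problems.extend(f"row {idx}: {p}" for p in hard)
            continue
        records.append(rec)
    if problems and strict:
        raise RecordValidationError(problems)
    return records


def age_group(age: int) -> str:
    """Five-year elderly age band: 65–69 … 85–89, then 90+."""
    if age < 65:
        raise ValueError(f"age {age} below the elderly cohort floor of 65")
    if age >= 90:
        return "90+"
    lo = 65 + 5 * ((age - 65) // 5)
    return f"{lo}-{lo + 4}"


def shift_discharge(record: AdmissionRecord, los: int) -> AdmissionRecord:
    """Copy of ``record`` with a new LOS and consistent discharge date."""
    return replace(
        record,
        los=los,
        discharge_date=record.admission_date + timedelta(days=los),
    )
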