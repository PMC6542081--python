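"""Read and validate patient-level one-day prescription charts.

A cohort file is the long-format chart extraction: one row per
prescription, patient attributes repeated on each row and checked for
consistency.  Patients younger than 65 are removed (and counted) on load,
mirroring the audit's inclusion rule.  Both regular and as-needed (PRN)
prescriptions are retained: a point-prevalence audit counts exposure, not
administration schedule.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .formulary import (
    DrugEntry,
    DrugRegistry,
    PsychotropicCategory,
    UnknownDrugError,
)

logger = logging.getLogger(__name__)

MIN_AGE = 65

COHORT_COLUMNS = ("patient_id", "age", "gender", "drug_name", "atc", "as_needed")
OPTIONAL_COLUMNS = ("dose", "time")


class CohortSchemaError(ValueError):
    """Malformed cohort file: missing columns or unparseable fields."""


@dataclass(frozen=True)
class Prescription:
    drug: DrugEntry
    as_needed: bool
    dose: Optional[str] = None
    administration_time: Optional[str] = None


@dataclass
class Patient:
    id: str
    age: int
    gender: str  # "F" or "M"
    prescriptions: list[Prescription] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gender not in {"F", "M"}:
            raise CohortSchemaError(
                f"patient {self.id!r}: gender must be F or M, got {self.gender!r}"
            )
        if self.age < 0:
            raise CohortSchemaError(f"patient {self.id!r}: negative age {self.age}")


@dataclass
class Cohort:
    label: str
    patients: list[Patient] = field(default_factory=list)
    excluded_count: int = 0

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def distinct_substances(patient: Patient) -> set[DrugEntry]:
    """Unique level-5 substances; regular + PRN of one drug count once."""
    return {p.drug for p in patient.prescriptions}


def category_registrations(patient: Patient) -> set[PsychotropicCategory]:
    """Categories with at least one prescribed substance (single
    registration per category, however many substances it contains)."""
    cats = {p.drug.category for p in patient.prescriptions}
    cats.discard(None)
    return cats  # type: ignore[return-value]


def read_cohort(
    path: Union[str, Path],
    registry: DrugRegistry,
    label: Optional[str] = None,
    skip_unknown_drugs: bool = False,
) -> Cohort:
    """Load, validate and age-filter a long-format cohort CSV.

    Parameters
    ----------
    path
        CSV with header ``patient_id,age,gender,drug_name,atc,as_needed``
        and optional ``dose,time`` columns; ``as_needed`` coded 0/1.
        A row with an empty ``drug_name`` registers a resident without
        psychotropics, keeping them in the cohort denominators.
    registry
        Every ``drug_name`` must resolve here (the stated ``atc`` column,
        when present, is cross-checked against the registry code).
    skip_unknown_drugs
        When True, rows whose drug is absent from the registry are dropped
        with a logged warning instead of raising.  Off by default because
        silent drops bias the indicator counts.
    """
    path = Path(path)
    label = label if label is not None else path.stem
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise CohortSchemaError(f"{path}: empty file, expected a header row")
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortSchemaError(f"{path}: missing columns {sorted(missing)}")
        rows = list(reader)

    patients: dict[str, Patient] = {}
    seen_rows: set[tuple] = set()
    for lineno, row in enumerate(rows, start=2):
        pid = row["patient_id"].strip()
        try:
            age = int(row["age"])
        except ValueError:
            raise CohortSchemaError(
                f"{path}:{lineno}: non-numeric age {row['age']!r} for patient {pid!r}"
            ) from None
        gender = row["gender"].strip().upper()
        drug_token = row["drug_name"].strip()
        if not drug_token:
            # registration-only row: a resident on no psychotropics
            if pid in patients:
                patient = patients[pid]
                if patient.age != age or patient.gender != gender:
                    raise CohortSchemaError(
                        f"{path}:{lineno}: inconsistent attributes for patient {pid!r}"
                    )
            else:
                patients[pid] = Patient(id=pid, age=age, gender=gender)
            continue
        try:
            drug = registry.lookup(row["drug_name"])
        except UnknownDrugError:
            if skip_unknown_drugs:
                logger.warning(
                    "%s:%d: skipping unknown drug %r for patient %r",
                    path,
                    lineno,
                    row["drug_name"],
                    pid,
                )
                continue
            raise
        stated_atc = row.get("atc", "").strip().upper()
        if stated_atc and stated_atc != drug.atc.code:
            raise CohortSchemaError(
                f"{path}:{lineno}: ATC {stated_atc} contradicts registry "
                f"({drug.name} is {drug.atc})"
            )
        as_needed_token = row["as_needed"].strip()
        if as_needed_token not in {"0", "1"}:
            raise CohortSchemaError(
                f"{path}:{lineno}: as_needed must be 0/1, got {as_needed_token!r}"
            )
        key = (pid, drug.name, as_needed_token)
        if key in seen_rows:
            logger.warning(
                "%s:%d: duplicate prescription row collapsed (%s, %s)",
                path,
                lineno,
                pid,
                drug.name,
            )
            continue
        seen_rows.add(key)

        if pid in patients:
            patient = patients[pid]
            if patient.age != age or patient.gender != gender:
                raise CohortSchemaError(
                    f"{path}:{lineno}: inconsistent attributes for patient {pid!r} "
                    f"(age {patient.age}/{age}, gender {patient.gender}/{gender})"
                )
        else:
            patient = Patient(id=pid, age=age, gender=gender)
            patients[pid] = patient
        patient.prescriptions.append(
            Prescription(
                drug=drug,
                as_needed=as_needed_token == "1",
                dose=row.get("dose") or None,
                administration_time=row.get("time") or None,
            )
        )

    kept = [p for p in patients.values() if p.age >= MIN_AGE]
    excluded = len(patients) - len(kept)
    if excluded:
        logger.info("%s: excluded %d patient(s) under %d", path, excluded, MIN_AGE)
    return Cohort(label=label, patients=kept, excluded_count=excluded)


def write_cohort(
    cohort: Cohort, path: Union[str, Path], include_optional: bool = False
) -> None:
    """Serialise a cohort back to the long-format CSV (deterministic order)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        header = list(COHORT_COLUMNS) + (list(OPTIONAL_COLUMNS) if include_optional else [])
        writer.writerow(header)
        for patient in cohort.patients:
            if not patient.prescriptions:
                # registration-only row keeps medication-free residents in
                # the cohort denominators
                row = [patient.id, patient.age, patient.gender, "", "", ""]
                if include_optional:
                    row += ["", ""]
                writer.writerow(row)
                continue
            for rx in patient.prescriptions:
                row = [
                    patient.id,
                    patient.age,
                    patient.gender,
                    rx.drug.name,
                    rx.drug.atc.code,
                    int(rx.as_needed),
                ]
                if include_optional:
                    row += [rx.dose or "", rx.administration_time or ""]
                writer.writerow(row)
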