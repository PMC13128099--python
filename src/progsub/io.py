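"""Tabular EHR dialect: four CSV tables, code maps, YAML config.

Tables (RFC-4180 CSV, UTF-8, ISO-8601 dates, day resolution):

* ``demographics.csv`` — patient_id, birth_date, sex, race_ethnicity
* ``diagnoses.csv``    — patient_id, date, code, code_system
* ``drugs.csv``        — patient_id, date, code, code_system
* ``vitals.csv``       — patient_id, date, bmi, systolic, diastolic, smoking

Duplicate (patient, date) rows are merged by set-union of codes; every
validation failure names the file, row and field involved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

TABLE_COLUMNS = {
    "demographics": ["patient_id", "birth_date", "sex", "race_ethnicity"],
    "diagnoses": ["patient_id", "date", "code", "code_system"],
    "drugs": ["patient_id", "date", "code", "code_system"],
    "vitals": ["patient_id", "date", "bmi", "systolic", "diastolic", "smoking"],
}

_ATC3_RE = re.compile(r"^[A-Z]\d{2}[A-Z]$")

UNMAPPED = "unmapped"


class CohortIOError(ValueError):
    """Raised on malformed input tables; message names file, row and field."""


@dataclass
class EncounterRecord:
    """All clinical events recorded for one patient on one calendar date."""

    patient_id: str
    date: pd.Timestamp
    diagnosis_codes: set = field(default_factory=set)
    drug_codes: set = field(default_factory=set)
    vitals: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """In-memory cohort: the four tables plus per-patient record streams."""

    demographics: pd.DataFrame
    diagnoses: pd.DataFrame
    drugs: pd.DataFrame
    vitals: pd.DataFrame

    def patient_ids(self) -> list:
        return sorted(self.demographics["patient_id"].astype(str))

    def records_for(self, patient_id: str) -> list:
        """Date-sorted, date-merged encounter records for one patient."""
        pid = str(patient_id)
        by_date: dict = {}

        def rec(date) -> EncounterRecord:
            return by_date.setdefault(date, EncounterRecord(pid, date))

        dx = self.diagnoses[self.diagnoses["patient_id"] == pid]
        for date, code in zip(dx["date"], dx["code"]):
            rec(date).diagnosis_codes.add(str(code))
        rx = self.drugs[self.drugs["patient_id"] == pid]
        for date, code in zip(rx["date"], rx["code"]):
            rec(date).drug_codes.add(str(code))
        vt = self.vitals[self.vitals["patient_id"] == pid]
        for _, row in vt.iterrows():
            r = rec(row["date"])
            for k in ("bmi", "systolic", "diastolic"):
                if pd.notna(row[k]):
                    r.vitals[k] = float(row[k])
            if pd.notna(row["smoking"]) and str(row["smoking"]):
                r.vitals["smoking"] = str(row["smoking"])
        return [by_date[d] for d in sorted(by_date)]

    def iter_patients(self) -> Iterator[tuple]:
        for pid in self.patient_ids():
            yield pid, self.records_for(pid)

    def demographics_for(self, patient_id: str) -> dict:
        row = self.demographics[
            self.demographics["patient_id"] == str(patient_id)
        ].iloc[0]
        return {
            "birth_date": row["birth_date"],
            "sex": str(row["sex"]),
            "race_ethnicity": str(row["race_ethnicity"]),
        }


def _read_table(path: Path, name: str, date_cols: list) -> pd.DataFrame:
    if not path.exists():
        raise CohortIOError(f"{path}: table '{name}' not found")
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in TABLE_COLUMNS[name]:
        if col not in df.columns:
            raise CohortIOError(f"{path}: missing required column '{col}'")
    for col in date_cols:
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise CohortIOError(
                f"{path}: unparseable date in column '{col}' at row {bad[0] + 2}"
            )
        df[col] = parsed
    return df


def read_cohort(directory) -> Cohort:
    """Read the four-table cohort from a directory."""
    d = Path(directory)
    demo = _read_table(d / "demographics.csv", "demographics", ["birth_date"])
    dx = _read_table(d / "diagnoses.csv", "diagnoses", ["date"])
    rx = _read_table(d / "drugs.csv", "drugs", ["date"])
    vt = _read_table(d / "vitals.csv", "vitals", ["date"])
    return Cohort(demo, dx, rx, vt)


def write_cohort(cohort: Cohort, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in TABLE_COLUMNS:
        df = getattr(cohort, name).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        df.to_csv(d / f"{name}.csv", index=False)


@dataclass
class CodeMap:
    """Many-to-one mapping of raw codes to target categories.

    Unmapped codes are routed to a single catch-all bucket and counted,
    never dropped, so the downstream feature dimension is stable.
    """

    source_system: str
    mapping: dict
    _unmapped_seen: set = field(default_factory=set)

    def apply(self, code: str) -> str:
        target = self.mapping.get(str(code))
        if target is None:
            self._unmapped_seen.add(str(code))
            return UNMAPPED
        return target

    def targets(self) -> list:
        return sorted(set(self.mapping.values())) + [UNMAPPED]

    def coverage(self, codes) -> float:
        codes = [str(c) for c in codes]
        if not codes:
            return 1.0
        return sum(c in self.mapping for c in codes) / len(codes)


def load_code_map(path, source_system: str, atc3: bool = False) -> CodeMap:
    """Load a two-column (source_code, target) CSV mapping.

    Duplicate source codes with conflicting targets are an error; for drug
    maps (``atc3=True``) every target must be a third-level ATC code
    (letter, two digits, letter).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("source_code", "target"):
        if col not in df.columns:
            raise CohortIOError(f"{path}: missing required column '{col}'")
    mapping: dict = {}
    for i, (src, tgt) in enumerate(zip(df["source_code"], df["target"])):
        src, tgt = str(src), str(tgt)
        if atc3 and not _ATC3_RE.match(tgt):
            raise CohortIOError(
                f"{path}: row {i + 2}: target '{tgt}' is not a 3rd-level ATC code"
            )
        if src in mapping and mapping[src] != tgt:
            raise CohortIOError(
                f"{path}: row {i + 2}: source code '{src}' maps to both "
                f"'{mapping[src]}' and '{tgt}'"
            )
        mapping[src] = tgt
    return CodeMap(source_system=source_system, mapping=mapping)


def packaged_code_maps() -> dict:
    """Small packaged mapping subsets (diagnosis→Phecode, drug→ATC-3)."""
    data = resources.files("progsub") / "data"
    return {
        "diagnosis": load_code_map(data / "icd_phecode_subset.csv", "ICD"),
        "drug": load_code_map(data / "rx_atc3_subset.csv", "RX", atc3=True),
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
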