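"""Claims data model: typed CSV schemas, readers/writers and validation.

A cohort is exchanged as a :class:`ClaimsBundle` — four linked tables
(patients, dispensings, diagnoses, encounters) keyed by an opaque
``patient_id``.  Files are UTF-8 CSVs with ISO-8601 calendar dates.  Coding
systems are abstracted into a small controlled vocabulary of semantic labels
(e.g. ``"mepolizumab"``, ``"asthma"``); a user-supplied code map can translate
external code systems into this vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: The five asthma biologics of interest.
BIOLOGICS = frozenset(
    {"benralizumab", "dupilumab", "mepolizumab", "omalizumab", "tezepelumab"}
)

#: Non-biologic drug classes tracked in dispensing records.
DRUG_CODES = BIOLOGICS | {
    "ics",
    "laba",
    "ics_laba",
    "lama",
    "ocs",
    "iv_steroid",
    "other",
}

#: Diagnosis labels: the qualifying condition, each exclusion condition, other.
DIAGNOSIS_CODES = frozenset(
    {
        "asthma",
        "lung_malignancy",
        "respiratory_tuberculosis",
        "cystic_fibrosis",
        "hypereosinophilic_syndrome",
        "egpa",
        "chronic_spontaneous_urticaria",
        "atopic_dermatitis",
        "prurigo_nodularis",
        "seasonal_allergic_rhinitis",
        "crswnp",
        "other",
    }
)

STEROID_COMPOUNDS = frozenset(
    {"prednisolone", "methylprednisolone", "hydrocortisone", "dexamethasone", "none"}
)

SEXES = frozenset({"male", "female"})
SMOKING_STATUSES = frozenset({"current_former", "never", "unknown"})
ENCOUNTER_TYPES = frozenset({"inpatient_admission", "ed_visit"})

TABLE_FILES = {
    "patients": "patients.csv",
    "dispensings": "dispensings.csv",
    "diagnoses": "diagnoses.csv",
    "encounters": "encounters.csv",
}

TABLE_COLUMNS = {
    "patients": [
        "patient_id",
        "birth_year",
        "sex",
        "enrollment_start",
        "enrollment_end",
        "smoking_status",
    ],
    "dispensings": [
        "patient_id",
        "drug_code",
        "dispense_date",
        "days_supplied",
        "quantity",
        "cost",
        "is_biologic",
        "steroid_compound",
    ],
    "diagnoses": ["patient_id", "code", "diagnosis_date"],
    "encounters": [
        "patient_id",
        "encounter_type",
        "start_date",
        "end_date",
        "asthma_related",
        "planned",
    ],
}

_DATE_COLUMNS = {
    "patients": ["enrollment_start", "enrollment_end"],
    "dispensings": ["dispense_date"],
    "diagnoses": ["diagnosis_date"],
    "encounters": ["start_date", "end_date"],
}

_BOOL_COLUMNS = {
    "dispensings": ["is_biologic"],
    "encounters": ["asthma_related", "planned"],
}

_NUMERIC_COLUMNS = {
    "patients": ["birth_year"],
    "dispensings": ["days_supplied", "quantity", "cost"],
}


class SchemaError(ValueError):
    """The on-disk files do not match the documented schema (fatal)."""


@dataclass(frozen=True)
class RowError:
    table: str
    line: int  # 1-based physical line number in the CSV (header = line 1)
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}.csv line {self.line}, column {self.column}: {self.message}"


class BundleReadError(ValueError):
    """Row-level parse errors, each carrying its table and line number."""

    def __init__(self, errors: list[RowError]):
        self.errors = errors
        super().__init__(
            "unreadable rows:\n" + "\n".join(str(e) for e in errors[:50])
        )


@dataclass(frozen=True)
class Violation:
    table: str
    row: int  # 0-based row index within the table
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def rules(self) -> set[str]:
        return {v.rule for v in self.violations}

    def __len__(self) -> int:
        return len(self.violations)


class BundleValidationError(ValueError):
    def __init__(self, report: ValidationReport):
        self.report = report
        lines = [f"{v.table}[{v.row}] {v.rule}: {v.message}" for v in report.violations[:50]]
        super().__init__("bundle failed validation:\n" + "\n".join(lines))


@dataclass
class ClaimsBundle:
    """The four linked claims tables for a cohort.

    Each attribute is a :class:`pandas.DataFrame` with the documented columns;
    dates are ``datetime64[ns]`` calendar dates and flags are plain booleans.
    """

    patients: pd.DataFrame
    dispensings: pd.DataFrame
    diagnoses: pd.DataFrame
    encounters: pd.DataFrame

    def counts(self) -> tuple[int, int, int, int]:
        return (
            len(self.patients),
            len(self.dispensings),
            len(self.diagnoses),
            len(self.encounters),
        )

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.patients.copy(),
            self.dispensings.copy(),
            self.diagnoses.copy(),
            self.encounters.copy(),
        )


def empty_bundle() -> ClaimsBundle:
    """A bundle with all four tables present but no rows."""
    tables = {}
    for name, cols in TABLE_COLUMNS.items():
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        for c in _DATE_COLUMNS.get(name, []):
            df[c] = pd.Series(dtype="datetime64[ns]")
        for c in _BOOL_COLUMNS.get(name, []):
            df[c] = pd.Series(dtype=bool)
        for c in _NUMERIC_COLUMNS.get(name, []):
            df[c] = pd.Series(dtype=float)
        tables[name] = df
    return ClaimsBundle(**tables)


def _parse_table(name: str, path: Path, errors: list[RowError]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = TABLE_COLUMNS[name]
    if list(df.columns) != expected:
        unknown = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        raise SchemaError(
            f"{path.name}: columns {list(df.columns)} do not match schema; "
            f"unknown={unknown}, missing={missing}"
        )
    out = df.copy()
    for col in _DATE_COLUMNS.get(name, []):
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        for idx in np.flatnonzero(parsed.isna().to_numpy()):
            errors.append(
                RowError(name, int(idx) + 2, col, f"unparseable date {df[col].iat[idx]!r}")
            )
        out[col] = parsed
    for col in _BOOL_COLUMNS.get(name, []):
        low = df[col].str.strip().str.lower()
        bad = ~low.isin(["true", "false"])
        for idx in np.flatnonzero(bad.to_numpy()):
            errors.append(
                RowError(name, int(idx) + 2, col, f"not a boolean: {df[col].iat[idx]!r}")
            )
        out[col] = low == "true"
    for col in _NUMERIC_COLUMNS.get(name, []):
        parsed = pd.to_numeric(df[col], errors="coerce")
        for idx in np.flatnonzero((parsed.isna() & (df[col] != "")).to_numpy()):
            errors.append(
                RowError(name, int(idx) + 2, col, f"not a number: {df[col].iat[idx]!r}")
            )
        out[col] = parsed
    # Negative costs are rejected at read time, with line numbers.
    if name == "dispensings":
        cost = out["cost"]
        for idx in np.flatnonzero((cost < 0).to_numpy()):
            errors.append(
                RowError(name, int(idx) + 2, "cost", f"negative cost {cost.iat[idx]}")
            )
    return out


def read_bundle(directory: str | Path) -> ClaimsBundle:
    """Read and validate the four schema CSVs from ``directory``.

    Raises :class:`FileNotFoundError` for a missing file, :class:`SchemaError`
    for a column mismatch and :class:`BundleReadError` (listing table, line
    number and offending value) for unparseable dates, non-numeric numerics or
    negative costs.  Row order is preserved.
    """
    directory = Path(directory)
    errors: list[RowError] = []
    tables = {}
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"missing required file {path}")
        tables[name] = _parse_table(name, path, errors)
    if errors:
        raise BundleReadError(errors)
    return ClaimsBundle(**tables)


def write_bundle(bundle: ClaimsBundle, directory: str | Path) -> Path:
    """Write a validated bundle to ``directory`` (created if needed).

    Refuses to write a bundle that fails :func:`validate_bundle`; reading the
    written directory back reproduces the bundle field-for-field.
    """
    report = validate_bundle(bundle)
    if not report.ok:
        raise BundleValidationError(report)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, fname in TABLE_FILES.items():
        df = bundle.table(name).copy()
        for col in _DATE_COLUMNS.get(name, []):
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        for col in _BOOL_COLUMNS.get(name, []):
            df[col] = df[col].map({True: "true", False: "false"})
        df.to_csv(directory / fname, index=False, encoding="utf-8")
    return directory


def _flag(report: list[Violation], table: str, mask, rule: str, message: str) -> None:
    for idx in np.flatnonzero(np.asarray(mask)):
        report.append(Violation(table, int(idx), rule, message))


def validate_bundle(bundle: ClaimsBundle) -> ValidationReport:
    """Check every typed invariant; violations are data, not exceptions."""
    v: list[Violation] = []
    pat, disp, diag, enc = (
        bundle.patients,
        bundle.dispensings,
        bundle.diagnoses,
        bundle.encounters,
    )

    _flag(v, "patients", pat["patient_id"].duplicated(), "unique_patient_id",
          "duplicate patient_id")
    _flag(v, "patients", pat["enrollment_start"] > pat["enrollment_end"],
          "enrollment_order", "enrollment_start after enrollment_end")
    _flag(v, "patients", ~pat["sex"].isin(SEXES), "sex_vocab", "unknown sex")
    _flag(v, "patients", ~pat["smoking_status"].isin(SMOKING_STATUSES),
          "smoking_vocab", "unknown smoking_status")

    _flag(v, "dispensings", ~disp["drug_code"].isin(DRUG_CODES), "drug_vocab",
          "unknown drug_code")
    _flag(v, "dispensings", disp["cost"] < 0, "nonnegative_cost", "negative cost")
    _flag(v, "dispensings", disp["days_supplied"] < 0, "nonnegative_days_supplied",
          "negative days_supplied")
    _flag(v, "dispensings", disp["is_biologic"] != disp["drug_code"].isin(BIOLOGICS),
          "biologic_flag", "is_biologic inconsistent with drug_code")
    _flag(v, "dispensings", ~disp["steroid_compound"].isin(STEROID_COMPOUNDS),
          "steroid_vocab", "unknown steroid_compound")

    _flag(v, "diagnoses", ~diag["code"].isin(DIAGNOSIS_CODES), "diagnosis_vocab",
          "unknown diagnosis code")

    _flag(v, "encounters", ~enc["encounter_type"].isin(ENCOUNTER_TYPES),
          "encounter_vocab", "unknown encounter_type")
    _flag(v, "encounters", enc["start_date"] > enc["end_date"], "encounter_order",
          "end_date before start_date")
    _flag(v, "encounters",
          (enc["encounter_type"] == "ed_visit") & enc["planned"],
          "ed_unplanned", "ED visit flagged as planned")

    known = set(pat["patient_id"])
    for name, df in (("dispensings", disp), ("diagnoses", diag), ("encounters", enc)):
        _flag(v, name, ~df["patient_id"].isin(known), "known_patient",
              "patient_id not present in patients table")

    return ValidationReport(v)


def load_codemap(path: str | Path) -> dict:
    """Load a YAML map from external code systems to the internal vocabulary.

    Expected shape::

        drug_codes:   {"620008xx": mepolizumab, ...}
        diagnosis_codes: {"J45": asthma, ...}
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out = {"drug_codes": dict(raw.get("drug_codes", {})),
           "diagnosis_codes": dict(raw.get("diagnosis_codes", {}))}
    for target in out["drug_codes"].values():
        if target not in DRUG_CODES:
            raise SchemaError(f"codemap maps to unknown drug code {target!r}")
    for target in out["diagnosis_codes"].values():
        if target not in DIAGNOSIS_CODES:
            raise SchemaError(f"codemap maps to unknown diagnosis code {target!r}")
    return out


def apply_codemap(bundle: ClaimsBundle, codemap: dict) -> ClaimsBundle:
    """Translate external codes to the internal vocabulary (non-destructive)."""
    out = bundle.copy()
    drug = codemap.get("drug_codes", {})
    diag = codemap.get("diagnosis_codes", {})
    if drug:
        out.dispensings["drug_code"] = out.dispensings["drug_code"].replace(drug)
        out.dispensings["is_biologic"] = out.dispensings["drug_code"].isin(BIOLOGICS)
    if diag:
        out.diagnoses["code"] = out.diagnoses["code"].replace(diag)
    return out
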