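"""Readers and writers for cohort files and assembled reports.

All tabular I/O is UTF-8 delimited text with the delimiter (comma or tab)
auto-detected from the header line.  Subject rows that fail validation are
collected into an exclusion list with a reason each — never silently
dropped — so that report metadata can account for every input row.
"""

from __future__ import annotations

import enum
import json
import logging
from pathlib import Path
from typing import NamedTuple, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .renal import Subject, convert_creatinine_umol_l
from .report import CohortReport
from .screening import DrugExposure

__all__ = [
    "CreatinineUnit",
    "RunConfig",
    "SchemaError",
    "SubjectsInput",
    "read_subjects",
    "read_exposures",
    "write_report",
    "read_report",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Raised when an input file does not match the expected schema."""


class CreatinineUnit(str, enum.Enum):
    MG_DL = "mg_dl"
    UMOL_L = "umol_l"


class RunConfig(BaseModel):
    """Configuration of one screening run."""

    subjects_path: Optional[Path] = None
    exposures_path: Optional[Path] = None
    rules_path: Optional[Path] = None
    output_path: Optional[Path] = None
    creatinine_unit: CreatinineUnit = CreatinineUnit.MG_DL
    mdrd_coefficient: float = Field(default=186.0, gt=0)
    hyperkalaemia_threshold_mmol_l: float = Field(default=5.5, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    seed: Optional[int] = None


class SubjectsInput(NamedTuple):
    subjects: list[Subject]
    exclusions: pd.DataFrame  # columns: subject_id, reason


_MANDATORY_SUBJECT_COLUMNS = [
    "subject_id",
    "age_years",
    "sex",
    "weight_kg",
    "serum_creatinine",
]
_OPTIONAL_SUBJECT_COLUMNS = [
    "serum_potassium_mmol_l",
    "override_cc_ml_min",
    "override_egfr",
]


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise SchemaError(f"{path}: empty file")
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype={"subject_id": str})


def read_subjects(
    path: Union[str, Path],
    unit: CreatinineUnit = CreatinineUnit.MG_DL,
) -> SubjectsInput:
    """Read a subjects table, applying unit conversion for creatinine.

    Expected header: subject_id, age_years, sex, weight_kg, serum_creatinine
    (optionally serum_creatinine_mg_dl), plus optional serum_potassium_mmol_l,
    override_cc_ml_min, override_egfr.  Rows failing validation are returned
    in the exclusion frame with reasons.
    """
    unit = CreatinineUnit(unit)
    df = _read_table(path)
    cols = set(df.columns)
    if "serum_creatinine_mg_dl" in cols and "serum_creatinine" not in cols:
        df = df.rename(columns={"serum_creatinine_mg_dl": "serum_creatinine"})
        cols = set(df.columns)
    missing = [c for c in _MANDATORY_SUBJECT_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    for c in _OPTIONAL_SUBJECT_COLUMNS:
        if c not in cols:
            df[c] = np.nan
    if df.empty:
        raise SchemaError(f"{path}: no subject rows")

    subjects: list[Subject] = []
    excluded: list[dict] = []
    for row in df.itertuples(index=False):
        sid = str(row.subject_id)
        scr = row.serum_creatinine
        if pd.notna(scr) and unit is CreatinineUnit.UMOL_L:
            scr = convert_creatinine_umol_l(float(scr))
        ov_cc = None if pd.isna(row.override_cc_ml_min) else float(row.override_cc_ml_min)
        ov_egfr = None if pd.isna(row.override_egfr) else float(row.override_egfr)
        if pd.isna(scr) and not (ov_cc is not None and ov_egfr is not None):
            excluded.append({"subject_id": sid, "reason": "missing serum creatinine"})
            continue
        if pd.isna(row.weight_kg) and ov_cc is None:
            excluded.append({"subject_id": sid, "reason": "missing anthropometrics"})
            continue
        try:
            subjects.append(
                Subject(
                    subject_id=sid,
                    age_years=float(row.age_years),
                    sex=str(row.sex),
                    weight_kg=None if pd.isna(row.weight_kg) else float(row.weight_kg),
                    serum_creatinine_mg_dl=None if pd.isna(scr) else float(scr),
                    serum_potassium_mmol_l=(
                        None
                        if pd.isna(row.serum_potassium_mmol_l)
                        else float(row.serum_potassium_mmol_l)
                    ),
                    override_cc_ml_min=ov_cc,
                    override_egfr=ov_egfr,
                )
            )
        except (ValueError, TypeError) as exc:
            excluded.append({"subject_id": sid, "reason": f"invalid row: {exc}"})
    exclusions = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    if excluded:
        logger.warning("%d subject row(s) excluded on validation", len(excluded))
    return SubjectsInput(subjects, exclusions)


def read_exposures(path: Union[str, Path]) -> list[DrugExposure]:
    """Read a drug-exposure table (subject_id, drug_name, times_per_week).

    Duplicate (subject, drug) rows are merged keeping the maximum
    times_per_week, with a warning.  Malformed counts raise a row error.
    """
    df = _read_table(path)
    needed = ["subject_id", "drug_name", "times_per_week"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    try:
        df["times_per_week"] = pd.to_numeric(df["times_per_week"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed times_per_week value ({exc})") from None
    if df["times_per_week"].isna().any() or (df["times_per_week"] < 0).any():
        bad = df.index[df["times_per_week"].isna() | (df["times_per_week"] < 0)][:5]
        raise SchemaError(
            f"{path}: missing or negative times_per_week in row(s) {list(bad + 2)}"
        )
    n_before = len(df)
    df = df.groupby(["subject_id", "drug_name"], as_index=False)["times_per_week"].max()
    if len(df) < n_before:
        logger.warning(
            "%d duplicate (subject, drug) exposure row(s) merged (max kept)",
            n_before - len(df),
        )
    return [
        DrugExposure(str(r.subject_id), str(r.drug_name), float(r.times_per_week))
        for r in df.itertuples(index=False)
    ]


def write_report(
    report: CohortReport,
    path: Union[str, Path],
    fmt: str = "json",
) -> list[Path]:
    """Write a report as one JSON document or a directory of TSV tables.

    JSON round-trips exactly through :func:`read_report`.  The TSV layout
    writes one file per table plus a metadata.json; percentages are rendered
    at 2 decimals, counts unrounded.
    """
    path = Path(path)
    if fmt == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(report.to_dict(), indent=1), encoding="utf-8")
        return [path]
    if fmt != "tsv":
        raise ValueError(f"unknown report format {fmt!r} (expected tsv or json)")
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for name in report._TABLES:
        df: pd.DataFrame = getattr(report, name)
        df = df.reset_index(drop=df.index.name is None)
        out = path / f"{name}.tsv"
        df.to_csv(out, sep="\t", index=False, float_format="%.2f")
        written.append(out)
    meta = path / "metadata.json"
    meta.write_text(json.dumps(report.metadata, indent=1), encoding="utf-8")
    written.append(meta)
    return written


def read_report(path: Union[str, Path]) -> CohortReport:
    """Parse a JSON report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return CohortReport.from_dict(payload)
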