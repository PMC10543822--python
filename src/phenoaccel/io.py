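"""Cohort and labs file I/O plus the inclusion filters.

Cohort tables are comma-separated UTF-8 CSV with a header row and period
decimal separator. The long-format labs table carries one analyte result
per row; the admission-panel filter keeps, per patient and analyte, the
result drawn closest to ICU admission within the first 24 hours, and
includes a patient only when all nine analytes are available.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .phenoage import BIOMARKERS, PANEL_COLUMNS, convert_to_canonical, PanelValidationError

__all__ = [
    "read_cohort", "write_cohort", "select_admission_panel",
    "exclude_readmissions", "CohortSchemaError",
]

log = logging.getLogger("phenoaccel")

#: Required cohort columns, in canonical write order.
REQUIRED_COLUMNS = [
    "patient_id", "hospitalization_id", "admission_order", "age_years",
    *PANEL_COLUMNS.values(),
    "died_in_hospital", "time_days",
]

_NUMERIC = ["age_years", *PANEL_COLUMNS.values(), "time_days"]


class CohortSchemaError(ValueError):
    """The cohort file violates the schema; message lists the problems."""


def read_cohort(path: str | Path, permissive: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Missing required columns raise :class:`CohortSchemaError` naming them.
    Malformed rows (non-numeric values in numeric columns, non-positive
    follow-up time) are collected and reported with row numbers; they abort
    the read unless ``permissive`` is set, in which case they are dropped
    with a logged warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    problems: list[str] = []
    bad = pd.Series(False, index=df.index)
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        mask = coerced.isna() & df[col].notna()
        for idx in df.index[mask]:
            problems.append(f"row {idx + 2}: non-numeric {col}={df.at[idx, col]!r}")
        bad |= mask | coerced.isna()
        df[col] = coerced
    nonpos = df["time_days"] <= 0
    for idx in df.index[nonpos.fillna(False)]:
        problems.append(f"row {idx + 2}: time_days must be positive")
    bad |= nonpos.fillna(False)
    if problems:
        if not permissive:
            raise CohortSchemaError("; ".join(problems))
        log.warning("dropping %d malformed row(s): %s", int(bad.sum()), "; ".join(problems))
        df = df.loc[~bad].reset_index(drop=True)
    df["died_in_hospital"] = df["died_in_hospital"].astype(int)
    df["admission_order"] = df["admission_order"].astype(int)
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Deterministic writer: stable column order, fixed float formatting."""
    ordered = [c for c in REQUIRED_COLUMNS if c in cohort.columns]
    ordered += [c for c in cohort.columns if c not in ordered]
    cohort[ordered].to_csv(path, index=False, float_format="%.10g")


#: Accepted analyte names in the long labs format.
LAB_ANALYTES = set(BIOMARKERS)


def select_admission_panel(
    labs: pd.DataFrame, window_hours: float = 24.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build one admission panel per patient from long-format lab results.

    Keeps results with sample time in [0, ``window_hours``] hours from ICU
    admission; per analyte the earliest (closest-to-admission) result wins.
    A patient is included only when all nine analytes are present; excluded
    patients get one recorded reason each. Values are converted to
    canonical units from the per-row unit code.

    Returns (panels, exclusions): ``panels`` has one row per included
    patient with the canonical panel columns; ``exclusions`` lists
    ``patient_id`` and ``reason``.
    """
    required = {"patient_id", "analyte", "value", "unit", "sample_time_h"}
    missing = required - set(labs.columns)
    if missing:
        raise CohortSchemaError(f"labs table missing column(s): {sorted(missing)}")
    unknown = set(labs["analyte"]) - LAB_ANALYTES
    if unknown:
        raise PanelValidationError(f"unknown analyte name(s): {sorted(unknown)}")

    inside = labs[(labs["sample_time_h"] >= 0) & (labs["sample_time_h"] <= window_hours)]
    panels, exclusions = [], []
    for pid, group in labs.groupby("patient_id", sort=True):
        g = inside[inside["patient_id"] == pid]
        present = set(g["analyte"])
        missing_analytes = sorted(LAB_ANALYTES - present)
        if missing_analytes:
            exclusions.append({
                "patient_id": pid,
                "reason": f"missing analyte(s) within window: {', '.join(missing_analytes)}",
            })
            continue
        row = {"patient_id": pid}
        for analyte, sub in g.groupby("analyte"):
            best = sub.loc[sub["sample_time_h"].idxmin()]
            row[PANEL_COLUMNS[analyte]] = convert_to_canonical(
                analyte, float(best["value"]), str(best["unit"])
            )
        panels.append(row)
    panel_df = pd.DataFrame(panels, columns=["patient_id", *PANEL_COLUMNS.values()])
    excl_df = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return panel_df, excl_df


def exclude_readmissions(cohort: pd.DataFrame) -> pd.DataFrame:
    """Keep only the first ICU admission within each hospitalization."""
    pairs = cohort[["hospitalization_id", "admission_order"]]
    if pairs.duplicated().any():
        dupes = pairs[pairs.duplicated()].drop_duplicates()
        raise CohortSchemaError(
            f"duplicate (hospitalization, order) pair(s): {dupes.to_dict('records')}"
        )
    first = cohort.groupby("hospitalization_id")["admission_order"].transform("min")
    kept = cohort[cohort["admission_order"] == first].reset_index(drop=True)
    log.info("readmission filter: %d of %d admissions retained", len(kept), len(cohort))
    return kept
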