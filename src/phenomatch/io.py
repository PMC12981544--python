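"""Readers and writers for the three delimited study tables.

All tables are plain CSV with a header row and ISO-8601 dates.  Encounter
note types are stored as a ``;``-joined list inside a single column.
Reading validates schemas and referential integrity, canonicalises
ICD-10-CM codes (dot-stripped, uppercase), and applies the study-window
and age filters; violations of those filters are dropped with a logged
count, not raised.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datamodel import (
    DIAGNOSIS_COLUMNS,
    ENCOUNTER_COLUMNS,
    PATIENT_COLUMNS,
    ReferentialIntegrityError,
    RunConfig,
    SchemaError,
    SEXES,
    canonical_code,
    completed_years,
    is_valid_code,
)

logger = logging.getLogger("phenomatch")


class Tables(NamedTuple):
    patients: pd.DataFrame
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {', '.join(missing)}")


def _parse_dates(df: pd.DataFrame, column: str) -> pd.DataFrame:
    df[column] = pd.to_datetime(df[column], format="ISO8601")
    return df


def read_tables(
    patients_path,
    encounters_path,
    diagnoses_path,
    config: RunConfig,
) -> Tables:
    """Read, validate and filter the patients/encounters/diagnoses tables.

    Returns the three tables with encounters outside the study window or
    outside the configured age range removed (together with their
    diagnoses).  Raises :class:`SchemaError` for missing columns and
    :class:`ReferentialIntegrityError` for dangling references.
    """
    patients = pd.read_csv(patients_path, dtype=str)
    encounters = pd.read_csv(encounters_path, dtype=str)
    diagnoses = pd.read_csv(diagnoses_path, dtype=str)

    _require_columns(patients, PATIENT_COLUMNS, "patients")
    _require_columns(encounters, ENCOUNTER_COLUMNS, "encounters")
    _require_columns(diagnoses, DIAGNOSIS_COLUMNS, "diagnoses")

    if patients["patient_id"].duplicated().any():
        dupes = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        raise ReferentialIntegrityError(f"duplicate patient_id values: {dupes[:10]}")

    patients = _parse_dates(patients, "birth_date")
    encounters = _parse_dates(encounters, "service_date")
    if "code_date" in diagnoses.columns:
        diagnoses = _parse_dates(diagnoses, "code_date")

    patients["sex"] = patients["sex"].str.lower().where(
        patients["sex"].str.lower().isin(SEXES[:2]), "unknown"
    )
    patients["race"] = patients["race"].fillna("unknown")
    if "latent_case" in patients.columns:
        patients["latent_case"] = patients["latent_case"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )

    # Referential integrity is checked before filtering so that dangling
    # references are reported even when the offending rows would be dropped.
    known_patients = set(patients["patient_id"])
    bad = encounters.loc[~encounters["patient_id"].isin(known_patients), "patient_id"]
    if len(bad):
        raise ReferentialIntegrityError(
            f"encounters reference unknown patient_id(s): {sorted(set(bad))[:10]}"
        )
    bad = diagnoses.loc[~diagnoses["patient_id"].isin(known_patients), "patient_id"]
    if len(bad):
        raise ReferentialIntegrityError(
            f"diagnoses reference unknown patient_id(s): {sorted(set(bad))[:10]}"
        )
    known_enc = set(encounters["encounter_id"])
    bad = diagnoses.loc[~diagnoses["encounter_id"].isin(known_enc), "encounter_id"]
    if len(bad):
        raise ReferentialIntegrityError(
            f"diagnoses reference unknown encounter_id(s): {sorted(set(bad))[:10]}"
        )

    encounters["note_types"] = encounters["note_types"].fillna("")

    diagnoses["code"] = diagnoses["code"].map(canonical_code)
    invalid = ~diagnoses["code"].map(is_valid_code)
    if invalid.any():
        logger.warning("dropping %d diagnoses with malformed codes", int(invalid.sum()))
        diagnoses = diagnoses[~invalid]

    encounters, diagnoses = filter_window_and_age(patients, encounters, diagnoses, config)

    # Invariant: code_date equals the linked encounter's service date.
    svc = encounters.set_index("encounter_id")["service_date"]
    linked = diagnoses["encounter_id"].map(svc)
    if "code_date" in diagnoses.columns:
        mismatched = int((diagnoses["code_date"] != linked).sum())
        if mismatched:
            logger.warning(
                "aligning %d diagnosis code_date values to encounter service dates", mismatched
            )
    diagnoses = diagnoses.assign(code_date=linked.values)

    return Tables(
        patients.reset_index(drop=True),
        encounters.reset_index(drop=True),
        diagnoses.reset_index(drop=True),
    )


def filter_window_and_age(
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop encounters outside the study window or the study age range.

    Idempotent: re-applying to already-filtered tables changes nothing.
    Diagnoses attached to dropped encounters are dropped as well.
    """
    start, end = (pd.Timestamp(d) for d in config.study_window)
    in_window = (encounters["service_date"] >= start) & (encounters["service_date"] <= end)

    birth = encounters["patient_id"].map(patients.set_index("patient_id")["birth_date"])
    ages = completed_years(birth.to_numpy(), encounters["service_date"].to_numpy())
    in_age = (ages >= config.age_min) & (ages <= config.age_max)

    keep = in_window & in_age
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "dropped %d encounters outside study window or age %d-%d",
            dropped,
            config.age_min,
            config.age_max,
        )
    encounters = encounters[keep]
    diagnoses = diagnoses[diagnoses["encounter_id"].isin(set(encounters["encounter_id"]))]
    return encounters, diagnoses


def write_tables(tables: Tables, out_dir) -> dict[str, Path]:
    """Write the three tables as CSV under *out_dir*; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in zip(("patients", "encounters", "diagnoses"), tables):
        paths[name] = write_report(df, out_dir / f"{name}.csv")
    return paths


def write_report(df: pd.DataFrame, path) -> Path:
    """Write a result table deterministically (stable column order and row sort).

    Dates are serialised as ISO-8601.  An empty frame yields a header-only
    file with a logged warning, so downstream stages can still open it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    if len(out) == 0:
        logger.warning("writing empty result set to %s", path)
    else:
        out = out.sort_values(list(out.columns), kind="stable")
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)
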