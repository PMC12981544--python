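"""Per-subject covariate matrix for propensity modelling.

One row per patient at an *index encounter*: for cases the first
encounter carrying a case-definition code, for comparators the last
(by default) in-window encounter.  Every feature aggregates only
information dated on or before the index date, so nothing from the
future leaks into the matrix.  Columns: age-band / sex / race
indicators, prior-encounter count, per-note-type counts, DSM-5
category indicators, and indicators for the selected comorbidity codes.
Patients matching the case definition never contribute comparator rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .casedef import Codeset, label_encounters
from .datamodel import NOTE_TYPES, RunConfig, SEXES, age_band_series, band_label
from .io import Tables

import logging

logger = logging.getLogger("phenomatch")

UNMAPPED = "unmapped"


@dataclass
class Dsm5Map:
    """Longest-prefix ICD-10 -> DSM-5 category mapping."""

    entries: tuple[tuple[str, str, bool], ...]  # (pattern-sans-*, category, is_prefix)

    @classmethod
    def from_file(cls, path) -> "Dsm5Map":
        df = pd.read_csv(path, dtype=str, comment="#")
        if not {"code_or_prefix", "category"} <= set(df.columns):
            raise ValueError("DSM-5 map needs columns 'code_or_prefix' and 'category'")
        entries = []
        for pat, cat in zip(df["code_or_prefix"], df["category"]):
            pat = str(pat).replace(".", "").strip().upper()
            if pat.endswith("*"):
                entries.append((pat[:-1], cat.strip(), True))
            else:
                entries.append((pat, cat.strip(), False))
        return cls(tuple(entries))

    def category(self, code: str) -> str:
        """Category of the longest matching entry; exact match outranks any prefix."""
        best, best_len = UNMAPPED, -1
        for pat, cat, is_prefix in self.entries:
            if is_prefix:
                if code.startswith(pat) and len(pat) > best_len:
                    best, best_len = cat, len(pat)
            elif code == pat and len(code) + 1 > best_len:
                # An exact entry outranks a prefix of the same length.
                best, best_len = cat, len(code) + 1
        return best

    def categories(self) -> list[str]:
        return sorted({cat for _, cat, _ in self.entries})

    def map_series(self, codes: pd.Series) -> pd.Series:
        uniq = pd.unique(codes)
        table = {c: self.category(c) for c in uniq}
        return codes.map(table)


def dsm5_category(code: str, mapping: Dsm5Map) -> str:
    """DSM-5 category for a canonical code; ``"unmapped"`` when absent."""
    return mapping.category(code)


def _index_encounters(
    tables: Tables,
    case_labels: pd.DataFrame,
    codeset: Codeset,
    comparator_index: str,
) -> pd.DataFrame:
    """Pick the index encounter per patient: first case-coded visit for
    cases, first/last in-window visit for comparators."""
    enc_labels = label_encounters(tables.encounters, tables.diagnoses, codeset)
    case_ids = set(case_labels.loc[case_labels["is_case"].astype(bool), "patient_id"])

    flagged = enc_labels[enc_labels["is_case"]]
    case_idx = (
        flagged.sort_values(["service_date", "encounter_id"], kind="stable")
        .drop_duplicates("patient_id")[["patient_id", "encounter_id", "service_date"]]
    )
    case_idx = case_idx[case_idx["patient_id"].isin(case_ids)].assign(is_case=True)

    comp = tables.encounters[~tables.encounters["patient_id"].isin(case_ids)]
    ascending = comparator_index == "first"
    comp_idx = (
        comp.sort_values(
            ["service_date", "encounter_id"], ascending=[ascending, ascending], kind="stable"
        )
        .drop_duplicates("patient_id")[["patient_id", "encounter_id", "service_date"]]
        .assign(is_case=False)
    )
    return pd.concat([case_idx, comp_idx], ignore_index=True)


def build_matrix(
    tables: Tables,
    case_labels: pd.DataFrame,
    covariates: Sequence[str],
    codeset: Codeset,
    dsm5_map: Dsm5Map,
    config: RunConfig,
) -> pd.DataFrame:
    """Assemble the feature matrix with an ``is_case`` label column.

    The column set is a deterministic function of the config, the DSM-5
    map, the covariate list and the observed race levels; rows are keyed
    by (patient_id, index_encounter_id).
    """
    bad = [c for c in covariates if codeset.match(c)]
    if bad:
        raise ValueError(f"case-definition codes cannot be covariates: {bad}")

    idx = _index_encounters(tables, case_labels, codeset, config.comparator_index)
    if len(idx) == 0:
        raise ValueError("no subjects with encounters; cannot build a feature matrix")

    patients = tables.patients.set_index("patient_id")
    idx = idx.merge(
        patients[["sex", "race", "birth_date"]], left_on="patient_id", right_index=True
    )
    idx["age_band"] = age_band_series(
        idx["birth_date"].to_numpy(), idx["service_date"].to_numpy(), config.age_bands
    ).to_numpy()

    out = pd.DataFrame(
        {
            "patient_id": idx["patient_id"].to_numpy(),
            "index_encounter_id": idx["encounter_id"].to_numpy(),
        }
    )
    for lo, hi in config.age_bands:
        lab = band_label(lo, hi)
        out[f"age_{lab}"] = (idx["age_band"] == lab).astype(int).to_numpy()
    for s in SEXES:
        out[f"sex_{s}"] = (idx["sex"] == s).astype(int).to_numpy()
    for r in sorted(tables.patients["race"].unique()):
        out[f"race_{r}"] = (idx["race"] == r).astype(int).to_numpy()

    # Utilization up to the index date: visits strictly before the index
    # encounter, plus note-type counts on visits up to and including it.
    enc = tables.encounters.merge(
        idx[["patient_id", "service_date"]].rename(columns={"service_date": "index_date"}),
        on="patient_id",
    )
    prior = (
        enc[enc["service_date"] < enc["index_date"]].groupby("patient_id").size()
    )
    out["n_prior_encounters"] = (
        out["patient_id"].map(prior).fillna(0).astype(int).to_numpy()
    )
    upto = enc[enc["service_date"] <= enc["index_date"]]
    for nt in NOTE_TYPES:
        counts = (
            upto[upto["note_types"].str.contains(nt, regex=False)]
            .groupby("patient_id")
            .size()
        )
        out[f"n_{nt}"] = out["patient_id"].map(counts).fillna(0).astype(int).to_numpy()

    # Diagnosis history up to the index date, case-definition codes excluded.
    diag = tables.diagnoses.loc[~codeset.match_mask(tables.diagnoses["code"])]
    diag = diag.merge(
        idx[["patient_id", "service_date"]].rename(columns={"service_date": "index_date"}),
        on="patient_id",
    )
    diag = diag[diag["code_date"] <= diag["index_date"]]
    diag = diag.assign(category=dsm5_map.map_series(diag["code"]))

    for cat in dsm5_map.categories():
        have = set(diag.loc[diag["category"] == cat, "patient_id"])
        out[f"dsm5_{cat}"] = out["patient_id"].isin(have).astype(int).to_numpy()
    for code in covariates:
        have = set(diag.loc[diag["code"] == code, "patient_id"])
        out[f"code_{code}"] = out["patient_id"].isin(have).astype(int).to_numpy()

    label_map = idx.set_index("patient_id")["is_case"]
    out["is_case"] = out["patient_id"].map(label_map).astype(bool).to_numpy()

    no_enc = set(tables.patients["patient_id"]) - set(out["patient_id"])
    if no_enc:
        logger.info("%d patients had no in-window encounters and produce no rows", len(no_enc))
    return out.sort_values("patient_id", kind="stable").reset_index(drop=True)


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Names of the model feature columns (ids and label excluded)."""
    return [c for c in matrix.columns if c not in ("patient_id", "index_encounter_id", "is_case")]
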