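"""Domain types and run configuration shared by every pipeline stage.

The pipeline operates on three delimited tables — patients, encounters,
diagnoses — held in memory as :class:`pandas.DataFrame` objects with the
column schemas declared here.  Dataclasses are used for configuration and
for small structured results; bulk data always lives in DataFrames.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import importlib.resources
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("phenomatch")

#: Canonical ICD-10-CM code shape after dot-stripping and uppercasing.
CODE_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]{1,5}$")

SEXES = ("male", "female", "unknown")
NOTE_TYPES = ("ed_note", "psychiatric_note", "discharge_summary")
#: Case subtypes in order of clinical severity.
CASE_SUBTYPES = ("ideation", "self_harm", "attempt")
#: Tags allowed in a codeset file; history-of-self-harm folds into self_harm.
CODESET_TAGS = CASE_SUBTYPES + ("history_of_self_harm",)

OUT_OF_RANGE = "out_of_range"

PATIENT_COLUMNS = ["patient_id", "sex", "race", "birth_date"]
ENCOUNTER_COLUMNS = ["encounter_id", "patient_id", "service_date", "note_types"]
DIAGNOSIS_COLUMNS = ["patient_id", "encounter_id", "code", "code_date"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ReferentialIntegrityError(ValueError):
    """A foreign key references a row that does not exist."""


def canonical_code(code: str) -> str:
    """Return the dot-stripped, uppercased ICD-10-CM form of *code*."""
    return str(code).replace(".", "").strip().upper()


def is_valid_code(code: str) -> bool:
    return bool(CODE_RE.match(code))


def completed_years(birth_date, on_date) -> np.ndarray:
    """Vectorised age in completed years at *on_date*.

    Accepts anything :func:`pandas.to_datetime` understands; returns an
    int64 array.  The (month, day) comparison handles the birthday
    boundary exactly: the age increments on the birthday itself.
    """
    b = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(birth_date)))
    o = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(on_date)))
    years = o.year - b.year
    before_birthday = (o.month < b.month) | ((o.month == b.month) & (o.day < b.day))
    return (years - before_birthday.astype(int)).to_numpy()


def band_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def age_band(birth_date, service_date, bands: Sequence[Sequence[int]]) -> str:
    """Map age in completed years at *service_date* to its band label.

    Bands are closed on both ends; an age outside every band yields the
    sentinel ``"out_of_range"``.
    """
    age = int(completed_years(birth_date, service_date)[0])
    for lo, hi in bands:
        if lo <= age <= hi:
            return band_label(lo, hi)
    return OUT_OF_RANGE


def age_band_series(birth_date, service_date, bands: Sequence[Sequence[int]]) -> pd.Series:
    """Vectorised :func:`age_band` over aligned date arrays."""
    ages = completed_years(birth_date, service_date)
    out = np.full(ages.shape, OUT_OF_RANGE, dtype=object)
    for lo, hi in bands:
        out[(ages >= lo) & (ages <= hi)] = band_label(lo, hi)
    return pd.Series(out)


def packaged_data(name: str) -> Path:
    """Path to a reference data file shipped inside the package."""
    return Path(importlib.resources.files("phenomatch") / "data" / name)


@dataclass
class RunConfig:
    """Configuration driving every pipeline stage.

    Parameters
    ----------
    study_window
        Inclusive [start, end] dates; encounters outside are dropped.
    age_bands
        Closed integer year bands; ages outside all bands are dropped.
    top_k
        Number of top-scoring co-occurring codes kept per stratum.
    min_patient_support
        Codes observed in fewer than this many patients are omitted
        (strictly fewer: a code at exactly the threshold is retained).
    alpha
        Family-wise significance level after Bonferroni correction.
    """

    study_window: tuple[_dt.date, _dt.date] = (_dt.date(2016, 6, 1), _dt.date(2022, 6, 1))
    age_bands: tuple[tuple[int, int], ...] = ((6, 11), (12, 18))
    top_k: int = 20
    min_patient_support: int = 20
    alpha: float = 0.05
    rng_seed: int = 0
    codeset_path: Optional[str] = None
    dsm5_map_path: Optional[str] = None
    yates: bool = True
    rank_by: str = "p_cond"  # or "chi2"
    comparator_index: str = "last"  # or "first"
    l2: float = 1e-4
    match_k: int = 1
    caliper: Optional[float] = None  # in logit units; None = no caliper
    match_with_replacement: bool = False

    def __post_init__(self) -> None:
        self.study_window = tuple(_coerce_date(d) for d in self.study_window)  # type: ignore[assignment]
        self.age_bands = tuple(tuple(int(x) for x in b) for b in self.age_bands)  # type: ignore[assignment]
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_patient_support < 1:
            raise ValueError("min_patient_support must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.rank_by not in ("p_cond", "chi2"):
            raise ValueError("rank_by must be 'p_cond' or 'chi2'")
        if self.comparator_index not in ("last", "first"):
            raise ValueError("comparator_index must be 'last' or 'first'")
        if self.study_window[0] > self.study_window[1]:
            raise ValueError("study window start exceeds end")

    @property
    def age_min(self) -> int:
        return min(lo for lo, _ in self.age_bands)

    @property
    def age_max(self) -> int:
        return max(hi for _, hi in self.age_bands)

    def resolved_codeset_path(self) -> Path:
        return Path(self.codeset_path) if self.codeset_path else packaged_data("suicidality_codeset.csv")

    def resolved_dsm5_path(self) -> Path:
        return Path(self.dsm5_map_path) if self.dsm5_map_path else packaged_data("dsm5_map.csv")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_window"] = [x.isoformat() for x in self.study_window]
        d["age_bands"] = [list(b) for b in self.age_bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc.get("run", doc))

    def log_effective(self, stage: str) -> None:
        logger.info("stage %s effective config: %s", stage, self.to_dict())


def _coerce_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return _dt.date.fromisoformat(str(d))
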