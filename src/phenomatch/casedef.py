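"""Suicidality case definition: codesets and case/subtype labelling.

A codeset is a named collection of exact ICD-10-CM codes and code
prefixes, each tagged with a subtype.  A patient (or encounter) is a
case when any of its diagnosis codes matches any entry; the matched
subtypes accumulate as a set.  History-of-self-harm codes count toward
case status and fold into the ``self_harm`` subtype, since documented
history of self-injury sits on the same behavioural continuum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datamodel import CASE_SUBTYPES, CODESET_TAGS, canonical_code

#: Codeset tags mapped onto the three analysis subtypes.
_TAG_TO_SUBTYPE = {
    "ideation": "ideation",
    "self_harm": "self_harm",
    "history_of_self_harm": "self_harm",
    "attempt": "attempt",
}


@dataclass(frozen=True)
class CodesetEntry:
    pattern: str  # canonical exact code, or prefix ending in '*'
    tag: str

    @property
    def is_prefix(self) -> bool:
        return self.pattern.endswith("*")


@dataclass
class Codeset:
    """Named set of exact codes and prefixes with subtype tags."""

    name: str
    entries: tuple[CodesetEntry, ...]
    _exact: dict = field(init=False, repr=False)
    _prefixes: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.pattern in seen:
                raise ValueError(f"duplicate codeset pattern {e.pattern!r}")
            seen.add(e.pattern)
            if e.tag not in CODESET_TAGS:
                raise ValueError(f"unknown subtype tag {e.tag!r} for {e.pattern!r}")
        exact: dict[str, set[str]] = {}
        prefixes: list[tuple[str, str]] = []
        for e in self.entries:
            subtype = _TAG_TO_SUBTYPE[e.tag]
            if e.is_prefix:
                prefixes.append((e.pattern[:-1], subtype))
            else:
                exact.setdefault(e.pattern, set()).add(subtype)
        self._exact = exact
        self._prefixes = tuple(prefixes)

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "Codeset":
        """Load a two-column CSV ``pattern,subtype``; ``CODE*`` marks a prefix."""
        df = pd.read_csv(path, dtype=str, comment="#")
        if not {"pattern", "subtype"} <= set(df.columns):
            raise ValueError("codeset file needs columns 'pattern' and 'subtype'")
        entries = tuple(
            CodesetEntry(_canonical_pattern(p), t.strip())
            for p, t in zip(df["pattern"], df["subtype"])
        )
        return cls(name or Path(path).stem, entries)

    def match(self, code: str) -> frozenset[str]:
        """Subtypes matched by a canonical code (union over all entries)."""
        subtypes = set(self._exact.get(code, ()))
        for prefix, subtype in self._prefixes:
            if code.startswith(prefix):
                subtypes.add(subtype)
        return frozenset(subtypes)

    def match_mask(self, codes: pd.Series) -> pd.Series:
        """Boolean mask: does each code match any entry?  Vectorised via uniques."""
        uniq = pd.unique(codes)
        hit = {c: bool(self.match(c)) for c in uniq}
        return codes.map(hit)

    def match_subtypes(self, codes: pd.Series) -> pd.Series:
        uniq = pd.unique(codes)
        table = {c: self.match(c) for c in uniq}
        return codes.map(table)


def _canonical_pattern(p: str) -> str:
    p = str(p).strip()
    if p.endswith("*"):
        return canonical_code(p[:-1]) + "*"
    return canonical_code(p)


def match_code(code: str, codeset: Codeset) -> frozenset[str]:
    """Set of subtypes the canonical *code* matches (possibly empty)."""
    return codeset.match(code)


def _matched_diagnoses(diagnoses: pd.DataFrame, codeset: Codeset) -> pd.DataFrame:
    d = diagnoses.loc[codeset.match_mask(diagnoses["code"])].copy()
    d["subtypes"] = codeset.match_subtypes(d["code"])
    return d


def label_patients(
    patients: pd.DataFrame, diagnoses: pd.DataFrame, codeset: Codeset
) -> pd.DataFrame:
    """One label per patient: is_case, subtype flags, first case-coded date.

    A patient is a case when any diagnosis on any encounter matches the
    codeset ("ever coded").  ``first_case_date`` is the earliest code_date
    carrying a matching code; patients with no diagnoses are non-cases.
    """
    matched = _matched_diagnoses(diagnoses, codeset)
    agg = (
        matched.groupby("patient_id")
        .agg(
            first_case_date=("code_date", "min"),
            subtypes=("subtypes", lambda s: frozenset().union(*s)),
        )
        .reset_index()
    )
    out = patients[["patient_id"]].merge(agg, on="patient_id", how="left")
    out["is_case"] = out["first_case_date"].notna()
    out["subtypes"] = out["subtypes"].where(out["is_case"], frozenset())
    return out[["patient_id", "is_case", "subtypes", "first_case_date"]]


def label_encounters(
    encounters: pd.DataFrame, diagnoses: pd.DataFrame, codeset: Codeset
) -> pd.DataFrame:
    """Per-encounter case/subtype flags from codes on that encounter only.

    A patient who is a case on some other encounter stays non-case here:
    the encounter grain reflects what was coded at that visit.
    """
    matched = _matched_diagnoses(diagnoses, codeset)
    agg = (
        matched.groupby("encounter_id")["subtypes"]
        .agg(lambda s: frozenset().union(*s))
        .rename("subtypes")
        .reset_index()
    )
    out = encounters[["encounter_id", "patient_id", "service_date"]].merge(
        agg, on="encounter_id", how="left"
    )
    out["is_case"] = out["subtypes"].notna()
    out["subtypes"] = out["subtypes"].where(out["is_case"], frozenset())
    return out


def subtypes_to_str(subtypes: frozenset[str]) -> str:
    """Stable serialisation of a subtype set, ordered by severity."""
    return "|".join(s for s in CASE_SUBTYPES if s in subtypes)


def labels_report(labels: pd.DataFrame) -> pd.DataFrame:
    out = labels.copy()
    out["subtypes"] = out["subtypes"].map(subtypes_to_str)
    return out
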