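"""Synthetic pediatric emergency-department EHR generator.

Emulates a multi-year ED population of patients aged 6-18 with a latent
per-patient suicidality status, planted conditional dependencies between
comorbidity codes and that status, and an under-coding mechanism: a
latent case receives a case-definition code with probability
``coding_sensitivity`` (sigma); non-latent patients never receive one.
Under-coding is modelled at the patient level — a latent case either is
or is not ever coded.

Each comorbidity code is assigned per patient by an independent
Bernoulli draw at its baseline rate ``rho0`` for non-latent patients and
``min(1, risk_ratio * rho0)`` for latent cases, then attached to a
uniformly chosen encounter.  The implied enrichment of a code B among
latent cases follows Bayes' rule:

    P(latent | B) = r*rho0*pi / (r*rho0*pi + rho0*(1 - pi))

which the generator's empirical output converges to as n grows.

Default rates are loosely calibrated to a large pediatric ED cohort:
overall latent prevalence 7%, coding sensitivity 53.4%, female and
adolescent patients at elevated relative risk (2x and 4x, renormalised
so the marginal prevalence stays at ``latent_prevalence``).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .casedef import Codeset
from .datamodel import RunConfig
from .io import Tables


@dataclass(frozen=True)
class CodeSpec:
    """A planted comorbidity code: baseline rate and latent risk ratio."""

    code: str
    rho0: float
    risk_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho0 <= 1.0):
            raise ValueError(f"rho0 out of [0,1] for {self.code}")
        if self.risk_ratio < 0:
            raise ValueError(f"risk_ratio < 0 for {self.code}")


#: Default planted comorbidities.  Baseline rates echo the relative
#: frequency of these disorder families in pediatric ED populations;
#: risk ratios are chosen so the implied P(case | code) spans the
#: 10-45% range typical of suicidality comorbidity profiles.
DEFAULT_COMORBIDITIES: tuple[CodeSpec, ...] = (
    CodeSpec("F329", 0.091, 6.8),     # major depressive disorder, single episode
    CodeSpec("F411", 0.156, 2.7),     # generalized anxiety disorder
    CodeSpec("F9090", 0.104, 1.7),    # ADHD, unspecified
    CodeSpec("F4310", 0.090, 2.3),    # post-traumatic stress disorder
    CodeSpec("F913", 0.061, 2.2),     # oppositional defiant disorder
    CodeSpec("G4700", 0.082, 1.8),    # insomnia
    CodeSpec("F603", 0.0032, 10.5),   # borderline personality disorder
    CodeSpec("F648", 0.0056, 10.0),   # gender dysphoria (other specified)
    CodeSpec("F319", 0.0075, 7.5),    # bipolar disorder, unspecified
    CodeSpec("F209", 0.0069, 6.4),    # schizophrenia, unspecified
    CodeSpec("F509", 0.021, 3.5),     # eating disorder, unspecified
    CodeSpec("F4489", 0.0039, 6.0),   # dissociative disorder
    CodeSpec("R440", 0.005, 5.0),     # auditory hallucinations
    CodeSpec("F489", 0.006, 5.0),     # nonpsychotic mental disorder, unspecified
    CodeSpec("T50901A", 0.010, 4.0),  # accidental poisoning, initial encounter
    CodeSpec("S51809A", 0.008, 3.5),  # laceration of forearm, initial encounter
    # Null codes: no dependence on latent status.
    CodeSpec("J069", 0.150, 1.0),     # upper respiratory infection
    CodeSpec("R509", 0.100, 1.0),     # fever
    CodeSpec("R109", 0.120, 1.0),     # abdominal pain
    CodeSpec("J45909", 0.080, 1.0),   # asthma, uncomplicated
    CodeSpec("S934", 0.050, 1.0),     # ankle sprain
    CodeSpec("B349", 0.070, 1.0),     # viral infection, unspecified
)

#: Representative case-definition code planted per drawn subtype.
SUBTYPE_CODES = {
    "ideation": "R45851",
    "self_harm": "X780XXA",
    "attempt": "T1491XA",
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic ED population.

    ``latent_prevalence`` is the marginal probability of latent
    suicidality; female and adolescent multipliers skew it across
    demographic strata while preserving the marginal.  ``subtype_mix``
    gives the probability that a coded case carries each subtype
    (subtypes may co-occur; a coded case with no drawn subtype defaults
    to ideation, the most common presentation).
    """

    n_patients: int = 20_000
    study_window: tuple[_dt.date, _dt.date] = (_dt.date(2016, 6, 1), _dt.date(2022, 6, 1))
    latent_prevalence: float = 0.07
    coding_sensitivity: float = 0.534
    comorbidity_spec: tuple[CodeSpec, ...] = DEFAULT_COMORBIDITIES
    subtype_mix: dict = field(
        default_factory=lambda: {"ideation": 0.862, "self_harm": 0.390, "attempt": 0.067}
    )
    sex_dist: dict = field(
        default_factory=lambda: {"male": 0.5165, "female": 0.4825, "unknown": 0.001}
    )
    race_dist: dict = field(
        default_factory=lambda: {
            "white": 0.45, "black": 0.20, "hispanic": 0.15, "asian": 0.08, "other": 0.12,
        }
    )
    child_fraction: float = 0.519  # ages 6-11 vs 12-18 at first encounter
    extra_encounter_rate: float = 0.52  # encounters per patient = 1 + Poisson(rate)
    female_multiplier: float = 2.0
    adolescent_multiplier: float = 4.0
    psych_note_prob_latent: float = 0.60
    psych_note_prob_other: float = 0.08
    discharge_note_prob: float = 0.30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("latent_prevalence", "coding_sensitivity", "child_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for s, p in self.subtype_mix.items():
            if s not in SUBTYPE_CODES or not (0.0 <= p <= 1.0):
                raise ValueError(f"bad subtype_mix entry {s}={p}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        self.comorbidity_spec = tuple(
            c if isinstance(c, CodeSpec) else CodeSpec(**c) for c in self.comorbidity_spec
        )
        self.study_window = tuple(
            d if isinstance(d, _dt.date) else _dt.date.fromisoformat(str(d))
            for d in self.study_window
        )  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc = doc.get("generator", doc)
        import dataclasses as _dc

        names = {f.name for f in _dc.fields(cls)}
        return cls(**{k: v for k, v in doc.items() if k in names})


def latent_probability(config: GeneratorConfig, female: np.ndarray, adolescent: np.ndarray) -> np.ndarray:
    """Per-patient latent probability with demographic multipliers.

    Multipliers are renormalised by their population mean so the marginal
    prevalence equals ``latent_prevalence`` regardless of the mix.
    """
    m = np.ones(len(female))
    m[female] *= config.female_multiplier
    m[adolescent] *= config.adolescent_multiplier
    p = config.latent_prevalence * m / m.mean()
    return np.clip(p, 0.0, 0.99)


def generate(config: GeneratorConfig) -> tuple[Tables, pd.DataFrame]:
    """Generate (patients, encounters, diagnoses) tables plus a truth table.

    All randomness comes from a single seeded stream, so generation is
    bit-reproducible at a fixed ``rng_seed``.  The truth table records
    ``latent_case`` and ``coded`` per patient; non-latent patients never
    receive case-definition codes.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_patients
    start, end = config.study_window
    window_days = (end - start).days

    pid = np.array([f"P{i:07d}" for i in range(n)])
    sexes = np.array(list(config.sex_dist))
    sex = rng.choice(sexes, size=n, p=_norm(list(config.sex_dist.values())))
    races = np.array(list(config.race_dist))
    race = rng.choice(races, size=n, p=_norm(list(config.race_dist.values())))

    # First encounter uniform in the window; age at that encounter drawn
    # per band.  Birth dates are placed so the completed-years age at the
    # first encounter equals the drawn age, with a safety margin so no
    # later encounter can cross the 19th birthday (the jitter keeps the
    # anniversary at least two days away from either band edge).
    first_off = rng.integers(0, window_days + 1, size=n)
    child = rng.random(n) < config.child_fraction
    age = np.where(child, rng.integers(6, 12, size=n), rng.integers(12, 19, size=n))
    jitter = rng.integers(2, 351, size=n)
    delta_first = np.round(365.25 * age).astype(int) + jitter
    first_date = pd.Timestamp(start) + pd.to_timedelta(first_off, unit="D")
    birth_date = first_date - pd.to_timedelta(delta_first, unit="D")

    # Latent status and coding.
    female = sex == "female"
    adolescent = age >= 12
    latent = rng.random(n) < latent_probability(config, female, adolescent)
    coded = latent & (rng.random(n) < config.coding_sensitivity)

    # Encounters: 1 + Poisson extra, later visits uniform between the
    # first visit and the earlier of window end / age-18 cap.
    extra = rng.poisson(config.extra_encounter_rate, size=n)
    n_enc = 1 + extra
    cap = np.minimum(window_days, first_off + (6935 - delta_first))
    cap = np.maximum(cap, first_off)
    total_enc = int(n_enc.sum())
    enc_patient_idx = np.repeat(np.arange(n), n_enc)
    enc_start = np.concatenate(([0], np.cumsum(n_enc)[:-1]))
    offs = rng.integers(
        first_off[enc_patient_idx], cap[enc_patient_idx] + 1, size=total_enc
    )
    offs[enc_start] = first_off  # the first encounter keeps its drawn date
    enc_id = np.array([f"E{i:08d}" for i in range(total_enc)])
    enc_dates = pd.Timestamp(start) + pd.to_timedelta(offs, unit="D")

    psych_p = np.where(latent[enc_patient_idx], config.psych_note_prob_latent,
                       config.psych_note_prob_other)
    has_psych = rng.random(total_enc) < psych_p
    has_discharge = rng.random(total_enc) < config.discharge_note_prob
    note_types = np.array([
        ";".join(
            ["ed_note"]
            + (["psychiatric_note"] if p else [])
            + (["discharge_summary"] if d else [])
        )
        for p, d in zip(has_psych, has_discharge)
    ])

    diag_pid: list[np.ndarray] = []
    diag_code: list[np.ndarray] = []
    diag_enc: list[np.ndarray] = []

    def _attach(patient_idx: np.ndarray, code: str) -> None:
        """Attach one instance of *code* to a random encounter per patient."""
        k = rng.integers(0, n_enc[patient_idx])
        enc_idx = enc_start[patient_idx] + k
        diag_pid.append(patient_idx)
        diag_code.append(np.full(len(patient_idx), code, dtype=object))
        diag_enc.append(enc_idx)

    # Case-definition codes: coded latent cases only.
    coded_idx = np.flatnonzero(coded)
    drew_any = np.zeros(len(coded_idx), dtype=bool)
    subtype_draws = {}
    for subtype, p in config.subtype_mix.items():
        d = rng.random(len(coded_idx)) < p
        subtype_draws[subtype] = d
        drew_any |= d
    subtype_draws["ideation"] = subtype_draws.get(
        "ideation", np.zeros(len(coded_idx), dtype=bool)
    ) | ~drew_any
    for subtype, drawn in subtype_draws.items():
        if drawn.any():
            _attach(coded_idx[drawn], SUBTYPE_CODES[subtype])

    # Planted comorbidity codes, conditionally independent given latent.
    for spec in config.comorbidity_spec:
        p = np.where(latent, min(1.0, spec.risk_ratio * spec.rho0), spec.rho0)
        drawn = np.flatnonzero(rng.random(n) < p)
        if len(drawn):
            _attach(drawn, spec.code)

    if diag_pid:
        dpi = np.concatenate(diag_pid)
        dei = np.concatenate(diag_enc)
        diagnoses = pd.DataFrame(
            {
                "patient_id": pid[dpi],
                "encounter_id": enc_id[dei],
                "code": np.concatenate(diag_code),
                "code_date": enc_dates[dei],
            }
        )
    else:  # pragma: no cover - only with an empty comorbidity spec and no cases
        diagnoses = pd.DataFrame(columns=["patient_id", "encounter_id", "code", "code_date"])
    diagnoses = diagnoses.sort_values(
        ["patient_id", "code_date", "code", "encounter_id"], kind="stable"
    ).reset_index(drop=True)

    patients = pd.DataFrame(
        {"patient_id": pid, "sex": sex, "race": race, "birth_date": birth_date}
    )
    encounters = pd.DataFrame(
        {
            "encounter_id": enc_id,
            "patient_id": pid[enc_patient_idx],
            "service_date": enc_dates,
            "note_types": note_types,
        }
    )
    truth = pd.DataFrame({"patient_id": pid, "latent_case": latent, "coded": coded})
    return Tables(patients, encounters, diagnoses), truth


def truth_summary(truth: pd.DataFrame, diagnoses: pd.DataFrame, codeset: Codeset) -> dict:
    """Coded-vs-latent confusion counts from the truth table and diagnoses."""
    if len(diagnoses):
        coded_patients = set(
            diagnoses.loc[codeset.match_mask(diagnoses["code"]), "patient_id"]
        )
    else:
        coded_patients = set()
    is_coded = truth["patient_id"].isin(coded_patients)
    latent = truth["latent_case"].astype(bool)
    return {
        "latent_coded": int((latent & is_coded).sum()),
        "latent_uncoded": int((latent & ~is_coded).sum()),
        "nonlatent_coded": int((~latent & is_coded).sum()),
        "nonlatent_uncoded": int((~latent & ~is_coded).sum()),
    }


def _norm(ps: list[float]) -> np.ndarray:
    a = np.asarray(ps, dtype=float)
    if (a < 0).any():
        raise ValueError("probabilities must be nonnegative")
    return a / a.sum()
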