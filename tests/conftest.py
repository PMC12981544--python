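import datetime as dt

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phenomatch.casedef import Codeset
from phenomatch.datamodel import RunConfig
from phenomatch.io import Tables
from phenomatch.synth import GeneratorConfig, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


def _ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def codeset() -> Codeset:
    return Codeset.from_file(RunConfig().resolved_codeset_path())


@pytest.fixture()
def tiny_tables() -> Tables:
    """Six hand-built patients exercising filters, labels and grains.

    P1: child case (depression then ideation), two encounters.
    P2: non-case with depression.
    P3: adolescent case, attempt coded on the *later* of two flagged visits.
    P4: non-case with a cold.
    P5: aged out (19 at her only encounter) -> filtered by read_tables.
    P6: one pre-window encounter (filtered) and one clean in-window visit.
    """
    patients = pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3", "P4", "P5", "P6"],
            "sex": ["female", "male", "female", "male", "female", "male"],
            "race": ["white", "black", "white", "other", "asian", "white"],
            "birth_date": [
                _ts("2008-01-01"), _ts("2006-01-01"), _ts("2004-07-15"),
                _ts("2010-03-03"), _ts("2002-05-01"), _ts("2007-09-09"),
            ],
        }
    )
    encounters = pd.DataFrame(
        {
            "encounter_id": ["E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8", "E9"],
            "patient_id": ["P1", "P1", "P2", "P3", "P3", "P4", "P5", "P6", "P6"],
            "service_date": [
                _ts("2018-05-01"), _ts("2019-03-01"), _ts("2018-06-01"),
                _ts("2020-01-10"), _ts("2019-05-01"), _ts("2019-07-04"),
                _ts("2021-06-01"), _ts("2016-01-01"), _ts("2018-09-09"),
            ],
            "note_types": [
                "ed_note", "ed_note;psychiatric_note", "ed_note",
                "ed_note", "ed_note;discharge_summary", "ed_note",
                "ed_note", "ed_note", "ed_note",
            ],
        }
    )
    diagnoses = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P2", "P3", "P3", "P4", "P5", "P6"],
            "encounter_id": ["E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8"],
            "code": ["F329", "R45851", "F329", "T1491XA", "T1491", "J069",
                     "F329", "F411"],
            "code_date": [
                _ts("2018-05-01"), _ts("2019-03-01"), _ts("2018-06-01"),
                _ts("2020-01-10"), _ts("2019-05-01"), _ts("2019-07-04"),
                _ts("2021-06-01"), _ts("2016-01-01"),
            ],
        }
    )
    return Tables(patients, encounters, diagnoses)


def write_tiny(tables: Tables, tmp_path):
    tmp_path.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in zip(("patients", "encounters", "diagnoses"), tables):
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        p = tmp_path / f"{name}.csv"
        out.to_csv(p, index=False)
        paths[name] = p
    return paths


@pytest.fixture(scope="session")
def small_synth():
    """A small generated population shared by read-only tests."""
    cfg = GeneratorConfig(n_patients=2000, rng_seed=7)
    tables, truth = generate(cfg)
    return cfg, tables, truth
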