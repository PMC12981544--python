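"""Conditional-probability comorbidity mining with significance screening.

For the case codeset A and every other observed code B, the score is the
conditional probability P(A|B) = P(A and B) / P(B), counted at patient
grain: n_joint patients carry both a case-definition code and B, out of
n_code patients carrying B.  Scores are computed overall and stratified
one axis at a time (age band, sex, case subtype), rare codes are
dropped, the top-k per stratum are kept, and each survivor is tested for
independence against case status with a 2x2 chi-square test under a
Bonferroni correction.  The union of significant codes across strata
becomes the covariate list for propensity modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .casedef import Codeset
from .datamodel import CASE_SUBTYPES, RunConfig, age_band_series, band_label
from .io import Tables

import logging

logger = logging.getLogger("phenomatch")


@dataclass(frozen=True)
class StratumSpec:
    """One stratification axis (or none, for the overall stratum).

    At most one of the three axes may be set.  ``age_band``/``sex``
    restrict the patient universe; ``subtype`` redefines the case event
    as that subtype while keeping the full universe.
    """

    age_band: Optional[str] = None
    sex: Optional[str] = None
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if sum(x is not None for x in (self.age_band, self.sex, self.subtype)) > 1:
            raise ValueError("at most one stratification axis per stratum")

    @property
    def label(self) -> str:
        if self.age_band:
            return f"age:{self.age_band}"
        if self.sex:
            return f"sex:{self.sex}"
        if self.subtype:
            return f"subtype:{self.subtype}"
        return "overall"


class Chi2Result(NamedTuple):
    chi2: float
    p_raw: float
    degenerate: bool


class ComorbidityAnalysis(NamedTuple):
    results: pd.DataFrame
    covariates: list[str]
    n_tests: int


def conditional_probability(n_joint: int, n_code: int) -> float:
    """P(case | code) = n_joint / n_code, in [0, 1].

    A value of 0 means the pair never co-occurs; 1 means the code always
    co-occurs with case status.
    """
    if n_code <= 0:
        raise ValueError("n_code must be positive (filtered upstream)")
    if n_joint > n_code:
        raise ValueError("n_joint cannot exceed n_code")
    return n_joint / n_code


def patient_strata_frame(
    patients: pd.DataFrame, encounters: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Per-patient stratification attributes (sex, age band at first visit).

    A patient can change age band across a multi-year window; the band at
    the first in-window encounter is the patient's stratum.
    """
    first = (
        encounters.sort_values(["service_date", "encounter_id"], kind="stable")
        .drop_duplicates("patient_id")[["patient_id", "service_date"]]
    )
    out = patients[["patient_id", "sex", "birth_date"]].merge(first, on="patient_id", how="inner")
    out["age_band"] = age_band_series(
        out["birth_date"].to_numpy(), out["service_date"].to_numpy(), config.age_bands
    ).to_numpy()
    return out[["patient_id", "sex", "age_band"]]


def cooccurrence_counts(
    diagnoses: pd.DataFrame,
    case_labels: pd.DataFrame,
    strata_frame: pd.DataFrame,
    stratum: StratumSpec,
    codeset: Codeset,
) -> pd.DataFrame:
    """Patient-grain (n_code, n_joint) per non-case-definition code.

    Case-definition codes are excluded from the B universe.  Returns one
    row per code observed in the stratum, with the stratum's case and
    patient totals repeated on every row (needed for the 2x2 test).
    """
    universe = strata_frame
    if stratum.age_band is not None:
        universe = universe[universe["age_band"] == stratum.age_band]
    if stratum.sex is not None:
        universe = universe[universe["sex"] == stratum.sex]
    pids = set(universe["patient_id"])

    labels = case_labels[case_labels["patient_id"].isin(pids)]
    if stratum.subtype is not None:
        case_flag = labels["subtypes"].map(lambda s: stratum.subtype in s)
    else:
        case_flag = labels["is_case"]
    case_ids = set(labels.loc[case_flag.astype(bool), "patient_id"])

    d = diagnoses[diagnoses["patient_id"].isin(pids)]
    d = d.loc[~codeset.match_mask(d["code"])]
    pairs = d[["patient_id", "code"]].drop_duplicates()
    n_code = pairs.groupby("code").size()
    n_joint = pairs[pairs["patient_id"].isin(case_ids)].groupby("code").size()

    out = pd.DataFrame({"n_code": n_code})
    out["n_joint"] = n_joint.reindex(out.index, fill_value=0).astype(int)
    out = out.reset_index().rename(columns={"index": "code"})
    out.insert(0, "stratum", stratum.label)
    out["n_cases"] = len(case_ids)
    out["n_total"] = len(pids)
    return out.sort_values("code", kind="stable").reset_index(drop=True)


def support_filter(results: pd.DataFrame, min_patient_support: int) -> pd.DataFrame:
    """Drop codes observed in fewer than *min_patient_support* patients.

    Strictly fewer: a code at exactly the threshold is retained.
    """
    return results[results["n_code"] >= min_patient_support].reset_index(drop=True)


def top_k(results: pd.DataFrame, k: int, score: str = "p_cond") -> pd.DataFrame:
    """Keep the k top-scoring codes per stratum.

    Ties break by n_joint descending, then lexicographic code, so the
    selection is deterministic.
    """
    ranked = results.sort_values(
        [score, "n_joint", "code"], ascending=[False, False, True], kind="stable"
    )
    return ranked.groupby("stratum", sort=False).head(k).reset_index(drop=True)


def chi_square_2x2(
    n_joint: int, n_code: int, n_cases: int, n_total: int, yates: bool = True
) -> Chi2Result:
    """Chi-square test of independence between code B and case status.

    The 2x2 table is reconstructed from the four patient counts:

        a = cases with B      b = cases without B
        c = non-cases with B  d = non-cases without B

    Yates continuity correction is applied by default (the conventional
    default of scientific-Python tooling for 2x2 tables).  A table with a
    zero marginal (hence a zero expected cell) is degenerate: the test
    carries no information and p_raw is reported as 1.
    """
    a = n_joint
    b = n_cases - n_joint
    c = n_code - n_joint
    d = n_total - n_cases - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts produce a negative 2x2 cell")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return Chi2Result(0.0, 1.0, True)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return Chi2Result(float(chi2), float(p), False)


def bonferroni(p_raw, m: int) -> np.ndarray:
    """Bonferroni correction: p_corrected = min(1, m * p_raw)."""
    p = np.asarray(p_raw, dtype=float)
    if m < len(p):
        raise ValueError("family size m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def default_strata(config: RunConfig) -> list[StratumSpec]:
    strata = [StratumSpec()]
    strata += [StratumSpec(age_band=band_label(lo, hi)) for lo, hi in config.age_bands]
    strata += [StratumSpec(sex=s) for s in ("male", "female")]
    strata += [StratumSpec(subtype=s) for s in CASE_SUBTYPES]
    return strata


def analyze(
    tables: Tables,
    case_labels: pd.DataFrame,
    codeset: Codeset,
    config: RunConfig,
    strata: Optional[Sequence[StratumSpec]] = None,
) -> ComorbidityAnalysis:
    """Run the full mining pipeline: count, filter, rank, test, correct.

    The processing order is fixed as support-filter then top-k, so a rare
    high-probability code can never crowd out a well-supported one.  The
    Bonferroni family is the set of tests actually reported: all top-k
    rows across strata.
    """
    strata = list(strata) if strata is not None else default_strata(config)
    sf = patient_strata_frame(tables.patients, tables.encounters, config)

    frames = []
    for stratum in strata:
        counts = cooccurrence_counts(tables.diagnoses, case_labels, sf, stratum, codeset)
        counts = support_filter(counts, config.min_patient_support)
        if len(counts) == 0:
            continue
        counts["p_cond"] = counts["n_joint"] / counts["n_code"]
        tested = counts.apply(
            lambda r: chi_square_2x2(
                int(r["n_joint"]), int(r["n_code"]), int(r["n_cases"]), int(r["n_total"]),
                yates=config.yates,
            ),
            axis=1,
            result_type="expand",
        )
        tested.columns = ["chi2", "p_raw", "degenerate"]
        counts = pd.concat([counts, tested], axis=1)
        frames.append(top_k(counts, config.top_k, score=config.rank_by))

    if not frames:
        empty = pd.DataFrame(
            columns=["stratum", "code", "n_code", "n_joint", "p_cond",
                     "chi2", "p_raw", "p_corrected", "significant"]
        )
        logger.warning("comorbidity analysis produced no testable codes")
        return ComorbidityAnalysis(empty, [], 0)

    results = pd.concat(frames, ignore_index=True)
    m = len(results)
    results["p_corrected"] = bonferroni(results["p_raw"].to_numpy(), m)
    results["significant"] = (results["p_corrected"] <= config.alpha) & ~results[
        "degenerate"
    ].astype(bool)
    logger.info("comorbidity analysis: %d tests in Bonferroni family", m)
    covariates = select_covariates(results, config.alpha)
    cols = ["stratum", "code", "n_code", "n_joint", "n_cases", "n_total",
            "p_cond", "chi2", "p_raw", "p_corrected", "degenerate", "significant"]
    return ComorbidityAnalysis(results[cols], covariates, m)


def select_covariates(results: pd.DataFrame, alpha: float) -> list[str]:
    """Deduplicated, sorted union of significant codes across strata."""
    if len(results) == 0:
        return []
    sig = results.loc[
        results["significant"].astype(bool) & (results["p_corrected"] <= alpha), "code"
    ]
    out = sorted(set(sig))
    if not out:
        logger.warning("no significant comorbidity codes; covariates will be "
                       "demographic/utilization only")
    return out
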