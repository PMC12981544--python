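"""Summary statistics and synthetic-truth scoring for a pipeline run.

Provides the worked-ratio arithmetic used throughout reporting
(prevalence percentages rounded half-away-from-zero to one decimal,
pooled two-proportion z test, Wald odds-ratio confidence intervals) and
the enrichment report that scores matching against the generator's
latent truth: if matching works, latent-but-uncoded cases should be
over-represented among matched comparators relative to the comparator
pool as a whole.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger("phenomatch")


def prevalence(numerator: int, denominator: int) -> float:
    """100 * n / d rounded half-away-from-zero to one decimal place."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator:
        raise ValueError("numerator cannot exceed denominator")
    x = 100.0 * numerator / denominator
    return math.floor(x * 10 + 0.5) / 10 if x >= 0 else -math.floor(-x * 10 + 0.5) / 10


def two_proportion_z(n1: int, N1: int, n2: int, N2: int) -> tuple[float, float]:
    """Pooled two-proportion z test; returns (z, two-sided p).

    z = (p1 - p2) / sqrt(p (1-p) (1/N1 + 1/N2)) with p the pooled
    proportion.  A pooled proportion of exactly 0 or 1 makes z undefined;
    then (nan, 1.0) is returned with a logged flag.
    """
    for n, N in ((n1, N1), (n2, N2)):
        if N <= 0 or not (0 <= n <= N):
            raise ValueError("counts must satisfy 0 <= n <= N, N > 0")
    pooled = (n1 + n2) / (N1 + N2)
    if pooled in (0.0, 1.0):
        logger.warning("two_proportion_z: degenerate pooled proportion %s", pooled)
        return float("nan"), 1.0
    z, p = proportions_ztest([n1, n2], [N1, N2], alternative="two-sided")
    return float(z), float(p)


def odds_ratio_ci(
    a: int, b: int, c: int, d: int, level: float = 0.95
) -> tuple[float, tuple[float, float], bool]:
    """Odds ratio ad/bc with a Wald confidence interval.

    Zero cells get the Haldane-Anscombe +0.5 correction to every cell;
    the returned flag marks when that was applied.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zq = stats.norm.ppf(0.5 + level / 2)
    lo, hi = math.exp(math.log(oratio) - zq * se), math.exp(math.log(oratio) + zq * se)
    return oratio, (lo, hi), corrected


def conditional_probability_table(
    results: pd.DataFrame, direction: str = "case_given_code"
) -> pd.DataFrame:
    """Tabulate P(case|code) or P(code|case) from comorbidity results."""
    out = results[["stratum", "code", "n_code", "n_joint", "n_cases"]].copy()
    if direction == "case_given_code":
        out["p"] = out["n_joint"] / out["n_code"]
    elif direction == "code_given_case":
        out["p"] = np.where(out["n_cases"] > 0, out["n_joint"] / out["n_cases"], np.nan)
    else:
        raise ValueError("direction must be 'case_given_code' or 'code_given_case'")
    return out


def enrichment_report(
    match_pairs: pd.DataFrame,
    comparator_ids: Sequence,
    truth: Optional[pd.DataFrame],
) -> dict:
    """Latent-case enrichment among matched comparators vs the whole pool.

    Reports latent prevalence among matched comparators and among all
    comparators, their ratio, and the two-proportion z test between the
    two groups.  Without a truth table (real data) the metrics are
    omitted with a notice; with no latent comparators at all (full
    coding sensitivity) the ratio is undefined and flagged.
    """
    if truth is None:
        logger.warning("no truth table available; enrichment metrics omitted")
        return {"available": False}
    latent = set(truth.loc[truth["latent_case"].astype(bool), "patient_id"])
    comparator_ids = list(comparator_ids)
    matched = list(dict.fromkeys(match_pairs["comparator_id"]))

    n_all = len(comparator_ids)
    k_all = sum(1 for c in comparator_ids if c in latent)
    n_matched = len(matched)
    k_matched = sum(1 for c in matched if c in latent)

    out: dict = {
        "available": True,
        "n_comparators": n_all,
        "n_latent_comparators": k_all,
        "n_matched_comparators": n_matched,
        "n_latent_matched": k_matched,
        "prev_all": k_all / n_all if n_all else None,
        "prev_matched": k_matched / n_matched if n_matched else None,
    }
    if not n_all or not k_all:
        logger.warning("no latent comparators; enrichment ratio undefined")
        out["enrichment_ratio"] = None
        out["degenerate"] = True
        return out
    out["degenerate"] = False
    if n_matched:
        out["enrichment_ratio"] = (k_matched / n_matched) / (k_all / n_all)
        z, p = two_proportion_z(k_matched, n_matched, k_all, n_all)
        out["z"], out["p"] = z, p
    else:
        out["enrichment_ratio"] = None
        out["z"], out["p"] = None, None
    return out


def latent_recall(match_pairs: pd.DataFrame, comparator_ids: Sequence,
                  truth: pd.DataFrame) -> Optional[float]:
    """Fraction of latent uncoded cases recovered inside the matched set."""
    latent = set(truth.loc[truth["latent_case"].astype(bool), "patient_id"])
    latent_comp = [c for c in comparator_ids if c in latent]
    if not latent_comp:
        return None
    matched = set(match_pairs["comparator_id"])
    return sum(1 for c in latent_comp if c in matched) / len(latent_comp)
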