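"""Propensity estimation, logit-space nearest-neighbour matching, balance.

A ridge-penalised logistic regression predicts case status from the
feature matrix; the predicted probability is the propensity score and
matching runs on its logit, where score differences near 0 and 1 are
magnified appropriately.  Matching is greedy 1:k nearest-neighbour
without replacement: cases are processed in a seeded random order and
each claims the unclaimed comparator(s) with the closest logit,
optionally within a caliper.  Balance is summarised by standardised
mean differences before and after matching.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger("phenomatch")

EPS = 1e-12


class ConvergenceError(RuntimeError):
    """The logistic solver failed to converge (e.g. complete separation)."""


@dataclass
class PropensityModel:
    coefficients: pd.Series  # indexed by feature name, on the original scale
    intercept: float
    l2: float
    converged: bool
    n_iter: int
    gradient_norm: float
    feature_names: list[str] = field(default_factory=list)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        z = self.intercept + X[self.feature_names].to_numpy(float) @ self.coefficients.to_numpy()
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # case_id, comparator_id, distance
    unmatched_cases: list
    scores: pd.Series  # propensity per subject id
    logits: pd.Series
    balance: Optional[pd.DataFrame] = None


def _binary_mask(X: np.ndarray) -> np.ndarray:
    mask = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        u = np.unique(X[:, j])
        mask[j] = len(u) <= 2 and np.isin(u, (0.0, 1.0)).all()
    return mask


def fit_propensity(
    X: pd.DataFrame,
    y: Sequence[bool],
    l2: float = 1e-4,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> PropensityModel:
    """Maximum penalised-likelihood logistic fit of case status on features.

    Non-binary columns are standardised internally (coefficients are
    reported back on the original scale); binary indicators are left
    as-is.  ``l2`` is the ridge strength on the standardised scale; with
    ``l2=0`` complete separation raises :class:`ConvergenceError`
    advising a positive penalty.  The fit is deterministic at fixed
    inputs — lbfgs with a fixed start, no stochastic initialisation.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least two rows in each class")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)

    binary = _binary_mask(Xv)
    mu = np.where(binary, 0.0, Xv.mean(axis=0))
    sd = np.where(binary, 1.0, Xv.std(axis=0))
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd

    if l2 > 0:
        clf = LogisticRegression(penalty="l2", C=1.0 / l2, solver="lbfgs",
                                 max_iter=max_iter, tol=tol)
    else:
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=max_iter, tol=tol)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)

    beta = clf.coef_[0]
    b0 = float(clf.intercept_[0])
    # Gradient of the penalised negative log-likelihood at the solution.
    p = 1.0 / (1.0 + np.exp(-(Xs @ beta + b0)))
    grad = Xs.T @ (p - y) + l2 * beta
    grad_norm = float(np.sqrt(grad @ grad + ((p - y).sum()) ** 2))
    n_iter = int(np.max(clf.n_iter_))
    # Complete separation: the unpenalised likelihood has no maximiser, the
    # solver walks the coefficients out until every fitted probability
    # saturates at its label.
    if l2 == 0 and np.abs(p - y).max() < 1e-4:
        raise ConvergenceError(
            f"complete separation: all fitted probabilities saturated "
            f"(|grad|={grad_norm:.3g}); set l2 > 0"
        )
    # lbfgs stopping at max_iter with a tiny residual gradient is still a
    # usable optimum (common with many collinear indicators).
    converged = np.isfinite(beta).all() and (
        n_iter < max_iter or grad_norm <= 1e-4 * max(1.0, len(y))
    )
    if not converged:
        msg = f"logistic fit did not converge (|grad|={grad_norm:.3g})"
        if l2 == 0:
            msg += "; possible complete separation — set l2 > 0"
        raise ConvergenceError(msg)

    coef_orig = beta / sd
    intercept_orig = b0 - float((beta * mu / sd).sum())
    return PropensityModel(
        coefficients=pd.Series(coef_orig, index=names),
        intercept=intercept_orig,
        l2=l2,
        converged=converged,
        n_iter=n_iter,
        gradient_norm=grad_norm,
        feature_names=names,
    )


def logit(p) -> np.ndarray:
    """ln(p / (1-p)) with scores clipped to [EPS, 1-EPS] first."""
    p = np.clip(np.atleast_1d(np.asarray(p, dtype=float)), EPS, 1.0 - EPS)
    return np.log(p / (1.0 - p))


def match(
    logits: pd.Series,
    case_ids: Sequence,
    comparator_ids: Sequence,
    k: int = 1,
    caliper: Optional[float] = None,
    seed: int = 0,
    with_replacement: bool = False,
) -> MatchResult:
    """Greedy nearest-neighbour matching on the logit scale.

    Cases are processed in a seeded random order; each claims its ``k``
    nearest unclaimed comparators by absolute logit distance (ties break
    toward the lower logit, then the lexicographically smaller id).  With
    a caliper, neighbours farther than ``caliper`` logits are refused and
    the case is recorded unmatched.  The result depends on the comparator
    *values*, never on their input order.
    """
    case_ids = list(case_ids)
    comparator_ids = list(comparator_ids)
    if not comparator_ids:
        raise ValueError("zero comparators: nothing to match against")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))

    pool = sorted(((float(logits[c]), str(c), c) for c in comparator_ids))
    keys = [p[0] for p in pool]

    pairs = []
    unmatched = []
    for i in order:
        cid = case_ids[i]
        target = float(logits[cid])
        claimed = []
        for _ in range(k):
            if not pool:
                break
            j = bisect.bisect_left(keys, target)
            cands = []
            if j < len(pool):
                cands.append((abs(pool[j][0] - target), pool[j][0], pool[j][1], j))
            if j > 0:
                cands.append((abs(pool[j - 1][0] - target), pool[j - 1][0], pool[j - 1][1], j - 1))
            dist, _, _, jbest = min(cands)
            if caliper is not None and dist > caliper:
                break
            claimed.append((cid, pool[jbest][2], dist))
            if not with_replacement:
                pool.pop(jbest)
                keys.pop(jbest)
        if claimed:
            pairs.extend(claimed)
        else:
            unmatched.append(cid)

    pairs_df = pd.DataFrame(pairs, columns=["case_id", "comparator_id", "distance"])
    if len(unmatched):
        logger.info("%d cases left unmatched", len(unmatched))
    scores = pd.Series(1.0 / (1.0 + np.exp(-logits)), index=logits.index)
    return MatchResult(
        pairs=pairs_df,
        unmatched_cases=unmatched,
        scores=scores,
        logits=logits.copy(),
    )


def score_distribution(
    scores: pd.Series,
    case_ids: Sequence,
    comparator_ids: Sequence,
    matched_comparator_ids: Optional[Sequence] = None,
    thresholds: tuple[float, float] = (0.5, 0.9),
) -> dict:
    """Fractions of each group below/above the score thresholds.

    Mirrors the usual before/after-matching summary: how many cases sit
    at high propensity, and how many comparators drop below 0.5.  Empty
    groups report ``None`` with a warning.
    """
    lo, hi = thresholds
    out = {}
    groups = {"cases": list(case_ids), "comparators": list(comparator_ids)}
    if matched_comparator_ids is not None:
        groups["matched_comparators"] = list(matched_comparator_ids)
    for name, ids in groups.items():
        if not ids:
            logger.warning("score_distribution: empty group %s", name)
            out[name] = {"frac_ge_hi": None, "frac_lt_lo": None, "n": 0}
            continue
        s = scores[ids].to_numpy()
        out[name] = {
            "frac_ge_hi": float((s >= hi).mean()),
            "frac_lt_lo": float((s < lo).mean()),
            "n": len(ids),
        }
    out["thresholds"] = {"lo": lo, "hi": hi}
    return out


def balance_table(
    X: pd.DataFrame,
    y: Sequence[bool],
    ids: Sequence,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Standardised mean difference per feature, before and after matching.

    SMD = (mean_case - mean_comparator) / pooled SD, with the pooled SD
    taken before matching; a zero pooled SD yields SMD 0 with a flag.
    The after column restricts to matched cases and their comparators.
    """
    y = np.asarray(y, dtype=bool)
    ids = pd.Index(ids)
    Xv = X.to_numpy(dtype=float)

    def smd(mask_case: np.ndarray, mask_comp: np.ndarray, pooled_sd: np.ndarray) -> np.ndarray:
        mc = Xv[mask_case].mean(axis=0)
        mo = Xv[mask_comp].mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = (mc - mo) / pooled_sd
        return np.where(pooled_sd == 0, 0.0, s)

    v_case = Xv[y].var(axis=0, ddof=1)
    v_comp = Xv[~y].var(axis=0, ddof=1)
    pooled = np.sqrt((v_case + v_comp) / 2.0)

    before = smd(y, ~y, pooled)
    matched_cases = ids.isin(set(pairs["case_id"]))
    matched_comps = ids.isin(set(pairs["comparator_id"]))
    after = (
        smd(matched_cases, matched_comps, pooled)
        if matched_cases.any() and matched_comps.any()
        else np.full(Xv.shape[1], np.nan)
    )
    return pd.DataFrame(
        {
            "feature": list(X.columns),
            "smd_before": before,
            "smd_after": after,
            "zero_sd": pooled == 0,
        }
    )
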