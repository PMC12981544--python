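import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phenomatch.propensity import (
    ConvergenceError,
    balance_table,
    fit_propensity,
    logit,
    match,
    score_distribution,
)


def simulate_logistic(n, beta, intercept, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(beta)))
    p = 1 / (1 + np.exp(-(X @ beta + intercept)))
    y = rng.random(n) < p
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(len(beta))]), y


class TestFitPropensity:
    def test_constant_feature_balanced_labels_gives_half(self):
        X = pd.DataFrame({"const": np.ones(200)})
        y = np.array([0, 1] * 100)
        model = fit_propensity(X, y, l2=1e-4)
        assert model.intercept == pytest.approx(0.0, abs=1e-3)
        p = model.predict_proba(X)
        assert np.allclose(p, 0.5, atol=1e-3)

    def test_recovers_known_coefficients(self):
        beta = np.array([0.8, -0.5, 0.3, 0.0, 1.0, -0.2])
        X, y = simulate_logistic(20_000, beta, -1.0, seed=42)
        model = fit_propensity(X, y)
        import statsmodels.api as sm

        sm_fit = sm.Logit(y.astype(int), sm.add_constant(X.to_numpy())).fit(disp=0)
        se = sm_fit.bse[1:]
        assert np.all(np.abs(model.coefficients.to_numpy() - beta) < 3 * se)

    def test_separation_raises_and_penalty_rescues(self):
        rng = np.random.default_rng(0)
        y = rng.random(100) < 0.5
        X = pd.DataFrame({"perfect": y.astype(float),
                          "noise": rng.standard_normal(100)})
        with pytest.raises(ConvergenceError, match="l2 > 0"):
            fit_propensity(X, y, l2=0.0)
        model = fit_propensity(X, y, l2=1.0)
        assert np.isfinite(model.coefficients).all()

    def test_needs_two_rows_per_class(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_propensity(X, [1, 1, 1])

    def test_deterministic_at_fixed_inputs(self):
        X, y = simulate_logistic(2000, np.array([0.5, -0.5]), 0.0, seed=7)
        m1 = fit_propensity(X, y)
        m2 = fit_propensity(X, y)
        pd.testing.assert_series_equal(m1.coefficients, m2.coefficients)


class TestLogit:
    def test_worked_values(self):
        assert logit(0.5)[0] == pytest.approx(0.0)
        assert logit(0.9)[0] == pytest.approx(np.log(9), abs=1e-12)
        assert logit(0.9)[0] == pytest.approx(2.19722, abs=1e-5)

    def test_extreme_scores_clipped_finite(self):
        assert np.isfinite(logit([0.0, 1.0])).all()

    @given(st.floats(1e-6, 1 - 1e-6))
    def test_antisymmetry(self, p):
        assert logit(p)[0] == pytest.approx(-logit(1 - p)[0], rel=1e-9, abs=1e-9)


def greedy_oracle(logits, case_ids, comparator_ids, order):
    """Quadratic greedy matcher with the documented tie-breaks."""
    remaining = {c: float(logits[c]) for c in comparator_ids}
    pairs = {}
    for i in order:
        cid = case_ids[i]
        if not remaining:
            break
        best = min(
            remaining.items(),
            key=lambda kv: (abs(kv[1] - float(logits[cid])), kv[1], str(kv[0])),
        )
        pairs[cid] = best[0]
        del remaining[best[0]]
    return pairs


class TestMatch:
    def test_nearest_neighbor_chosen(self):
        logits = pd.Series({"case": 0.0, "far": -5.0, "near": 0.1})
        res = match(logits, ["case"], ["far", "near"], seed=0)
        assert res.pairs.iloc[0]["comparator_id"] == "near"
        assert res.pairs.iloc[0]["distance"] == pytest.approx(0.1)

    def test_without_replacement_leaves_case_unmatched(self):
        logits = pd.Series({"c1": 0.0, "c2": 0.2, "m1": 0.1})
        res = match(logits, ["c1", "c2"], ["m1"], seed=0)
        assert len(res.pairs) == 1
        assert len(res.unmatched_cases) == 1

    def test_zero_comparators_is_error(self):
        with pytest.raises(ValueError, match="comparator"):
            match(pd.Series({"c": 0.0}), ["c"], [], seed=0)

    def test_caliper_refuses_distant_matches(self):
        logits = pd.Series({"case": 0.0, "far": 3.0})
        res = match(logits, ["case"], ["far"], caliper=0.5, seed=0)
        assert len(res.pairs) == 0 and res.unmatched_cases == ["case"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        case_ids = [f"c{i}" for i in range(50)]
        comp_ids = [f"m{i}" for i in range(500)]
        logits = pd.Series(
            np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 500)]),
            index=case_ids + comp_ids,
        )
        seed = 99
        res = match(logits, case_ids, comp_ids, seed=seed)
        order = np.random.default_rng(seed).permutation(len(case_ids))
        expected = greedy_oracle(logits, case_ids, comp_ids, order)
        got = dict(zip(res.pairs["case_id"], res.pairs["comparator_id"]))
        assert got == expected
        # Greedy total distance beats a random assignment of the same pool.
        rand_comp = rng.choice(comp_ids, size=50, replace=False)
        rand_total = sum(abs(logits[c] - logits[m]) for c, m in zip(case_ids, rand_comp))
        assert res.pairs["distance"].sum() <= rand_total

    def test_invariant_to_comparator_input_order(self):
        rng = np.random.default_rng(8)
        case_ids = [f"c{i}" for i in range(20)]
        comp_ids = [f"m{i}" for i in range(100)]
        logits = pd.Series(rng.normal(size=120), index=case_ids + comp_ids)
        r1 = match(logits, case_ids, comp_ids, seed=3)
        r2 = match(logits, case_ids, list(reversed(comp_ids)), seed=3)
        pd.testing.assert_frame_equal(r1.pairs, r2.pairs)

    def test_one_to_one_pairing(self):
        rng = np.random.default_rng(2)
        case_ids = [f"c{i}" for i in range(30)]
        comp_ids = [f"m{i}" for i in range(60)]
        logits = pd.Series(rng.normal(size=90), index=case_ids + comp_ids)
        res = match(logits, case_ids, comp_ids, seed=1)
        assert res.pairs["comparator_id"].is_unique
        assert res.pairs["case_id"].is_unique
        assert (res.pairs["distance"] >= 0).all()


class TestScoreDistribution:
    def test_all_high_scores(self):
        scores = pd.Series({"a": 0.95, "b": 0.95})
        out = score_distribution(scores, ["a", "b"], [])
        assert out["cases"]["frac_ge_hi"] == 1.0
        assert out["comparators"]["frac_ge_hi"] is None  # empty group flagged

    def test_fractions_partition(self):
        scores = pd.Series({"a": 0.95, "b": 0.3, "c": 0.6})
        out = score_distribution(scores, [], ["a", "b", "c"])
        g = out["comparators"]
        assert g["frac_ge_hi"] == pytest.approx(1 / 3)
        assert g["frac_lt_lo"] == pytest.approx(1 / 3)


class TestBalanceTable:
    def test_identical_groups_zero_smd(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0]})
        y = [True, True, False, False]
        pairs = pd.DataFrame({"case_id": ["a"], "comparator_id": ["c"],
                              "distance": [0.0]})
        bal = balance_table(X, y, ["a", "b", "c", "d"], pairs)
        assert bal["smd_before"].iloc[0] == pytest.approx(0.0)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"f": np.concatenate([rng.normal(1, 1, 2000),
                                               rng.normal(0, 1, 2000)])})
        y = np.array([True] * 2000 + [False] * 2000)
        ids = [f"s{i}" for i in range(4000)]
        pairs = pd.DataFrame({"case_id": ids[:10], "comparator_id": ids[2000:2010],
                              "distance": [0.0] * 10})
        bal = balance_table(X, y, ids, pairs)
        assert bal["smd_before"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_zero_sd_flagged(self):
        X = pd.DataFrame({"f": [1.0, 1.0, 1.0, 1.0]})
        y = [True, True, False, False]
        pairs = pd.DataFrame({"case_id": ["a"], "comparator_id": ["c"],
                              "distance": [0.0]})
        bal = balance_table(X, y, ["a", "b", "c", "d"], pairs)
        assert bool(bal["zero_sd"].iloc[0]) and bal["smd_before"].iloc[0] == 0.0

    def test_matching_on_true_propensity_improves_balance(self):
        """Over several seeds, matching reduces mean |SMD| on planted data."""
        improved = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 1500
            x = rng.standard_normal(n)
            p = 1 / (1 + np.exp(-(x - 1.5)))
            y = rng.random(n) < p
            if y.sum() < 10 or (~y).sum() < 10:
                continue
            ids = [f"s{i}" for i in range(n)]
            logits = pd.Series(x - 1.5, index=ids)
            case_ids = [i for i, flag in zip(ids, y) if flag]
            comp_ids = [i for i, flag in zip(ids, y) if not flag]
            res = match(logits, case_ids, comp_ids, seed=seed)
            bal = balance_table(pd.DataFrame({"x": x}), y, ids, res.pairs)
            if abs(bal["smd_after"].iloc[0]) < abs(bal["smd_before"].iloc[0]):
                improved += 1
        assert improved >= 9
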