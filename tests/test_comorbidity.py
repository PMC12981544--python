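import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from phenomatch.casedef import label_patients
from phenomatch.comorbidity import (
    StratumSpec,
    analyze,
    bonferroni,
    chi_square_2x2,
    conditional_probability,
    cooccurrence_counts,
    patient_strata_frame,
    select_covariates,
    support_filter,
    top_k,
)
from phenomatch.datamodel import RunConfig
from phenomatch.synth import CodeSpec, GeneratorConfig, generate


def chi2_textbook(a, b, c, d, yates):
    """Closed-form 2x2 chi-square: N(|ad-bc| - N/2)^2 / row/col products."""
    N = a + b + c + d
    num = abs(a * d - b * c) - (N / 2 if yates else 0)
    num = max(num, 0.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return N * num**2 / denom


def brute_force_counts(diagnoses, case_ids, codeset, patient_ids):
    """Exhaustive set-intersection oracle over per-patient code sets."""
    sub = diagnoses[diagnoses["patient_id"].isin(set(patient_ids))]
    codes_by_patient = {
        pid: set(g) for pid, g in sub.groupby("patient_id")["code"]
    }
    all_codes = sorted(
        {c for s in codes_by_patient.values() for c in s if not codeset.match(c)}
    )
    out = {}
    for code in all_codes:
        with_b = {p for p, s in codes_by_patient.items() if code in s}
        out[code] = (len(with_b), len(with_b & set(case_ids)))
    return out


class TestConditionalProbability:
    @pytest.mark.parametrize(
        "n_joint,n_code,expected",
        [
            (84, 190, 0.442),   # personality-disorder worked ratio
            (143, 333, 0.429),  # gender-dysphoria worked ratio
            (0, 50, 0.0),       # never co-occur
            (50, 50, 1.0),      # always co-occur
        ],
    )
    def test_worked_ratios(self, n_joint, n_code, expected):
        assert round(conditional_probability(n_joint, n_code), 3) == expected

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            conditional_probability(1, 0)
        with pytest.raises(ValueError):
            conditional_probability(5, 4)


class TestCooccurrenceCounts:
    def test_shared_code_counts(self, tiny_tables, codeset, run_config):
        labels = label_patients(tiny_tables.patients, tiny_tables.diagnoses, codeset)
        sf = patient_strata_frame(tiny_tables.patients, tiny_tables.encounters, run_config)
        counts = cooccurrence_counts(
            tiny_tables.diagnoses, labels, sf, StratumSpec(), codeset
        ).set_index("code")
        # F329 carried by P1 (case), P2 and P5 -> n_code 3, n_joint 1.
        assert counts.loc["F329", "n_code"] == 3
        assert counts.loc["F329", "n_joint"] == 1
        # Case-definition codes are excluded from the B universe.
        assert "R45851" not in counts.index
        assert "T1491XA" not in counts.index

    def test_matches_brute_force_oracle_on_small_population(self, codeset, run_config):
        cfg = GeneratorConfig(n_patients=200, rng_seed=21)
        tables, _ = generate(cfg)
        labels = label_patients(tables.patients, tables.diagnoses, codeset)
        sf = patient_strata_frame(tables.patients, tables.encounters, run_config)
        case_ids = set(labels.loc[labels["is_case"], "patient_id"])

        for stratum in (StratumSpec(), StratumSpec(sex="female"),
                        StratumSpec(age_band="12-18")):
            got = cooccurrence_counts(tables.diagnoses, labels, sf, stratum, codeset)
            universe = sf
            if stratum.sex:
                universe = universe[universe["sex"] == stratum.sex]
            if stratum.age_band:
                universe = universe[universe["age_band"] == stratum.age_band]
            expected = brute_force_counts(
                tables.diagnoses, case_ids, codeset, universe["patient_id"]
            )
            assert dict(zip(got["code"], zip(got["n_code"], got["n_joint"]))) == expected


class TestSupportFilter:
    def test_strictly_fewer_than_threshold_removed(self):
        df = pd.DataFrame({"code": ["A001", "B001", "C001"],
                           "n_code": [19, 20, 21], "n_joint": [1, 2, 3]})
        kept = support_filter(df, 20)
        assert list(kept["code"]) == ["B001", "C001"]

    def test_threshold_one_is_identity(self):
        df = pd.DataFrame({"code": ["A001"], "n_code": [1], "n_joint": [0]})
        pd.testing.assert_frame_equal(support_filter(df, 1), df)


class TestTopK:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["stratum", "code", "n_code", "n_joint", "p_cond"])

    def test_ranking_contract(self):
        rows = [("overall", f"A{i:03d}", 100, i, i / 100) for i in range(25)]
        out = top_k(self._frame(rows), 20)
        assert len(out) == 20
        assert out["p_cond"].min() >= 5 / 100  # the 5 lowest scores were excluded

    def test_fewer_rows_than_k_all_kept(self):
        rows = [("overall", f"A{i:03d}", 50, i, i / 50) for i in range(5)]
        assert len(top_k(self._frame(rows), 20)) == 5

    def test_tie_breaks_exhaustively(self):
        # Equal p_cond at the boundary: higher n_joint wins, then code order.
        rows = [
            ("overall", "B001", 40, 20, 0.5),
            ("overall", "A001", 20, 10, 0.5),
            ("overall", "C001", 10, 5, 0.5),
            ("overall", "D001", 10, 9, 0.9),
        ]
        out = top_k(self._frame(rows), 2)
        assert list(out["code"]) == ["D001", "B001"]
        # Among the 0.5 ties the max n_joint is selected first; with equal
        # n_joint as well, the lexicographically smaller code wins.
        rows[0] = ("overall", "B001", 20, 10, 0.5)
        out = top_k(self._frame(rows), 2)
        assert list(out["code"]) == ["D001", "A001"]

    def test_per_stratum_selection(self):
        rows = [("s1", "A001", 30, 3, 0.1), ("s1", "B001", 30, 6, 0.2),
                ("s2", "C001", 30, 9, 0.3)]
        out = top_k(self._frame(rows), 1)
        assert set(out["code"]) == {"B001", "C001"}


class TestChiSquare:
    @pytest.mark.parametrize("yates", [False, True])
    @pytest.mark.parametrize(
        "cells",
        [(10, 20, 30, 40), (5, 95, 50, 850), (1, 1, 1, 97), (14, 700, 190, 19000)],
    )
    def test_matches_textbook_closed_form(self, cells, yates):
        a, b, c, d = cells
        n_joint, n_cases, n_code, n_total = a, a + b, a + c, a + b + c + d
        got = chi_square_2x2(n_joint, n_code, n_cases, n_total, yates=yates)
        expected = chi2_textbook(a, b, c, d, yates)
        assert got.chi2 == pytest.approx(expected, abs=1e-8)
        assert got.p_raw == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-8)

    def test_uncorrected_worked_value(self):
        # [[10,20],[30,40]] without correction: 100*(400-600)^2/(30*70*40*60).
        got = chi_square_2x2(10, 40, 30, 100, yates=False)
        assert got.chi2 == pytest.approx(0.7936507936507936, abs=1e-12)

    def test_independent_table_gives_zero(self):
        got = chi_square_2x2(10, 20, 20, 40, yates=False)
        assert got.chi2 == 0.0 and got.p_raw == 1.0

    def test_degenerate_marginal_flagged(self):
        got = chi_square_2x2(0, 0, 10, 100)
        assert got.degenerate and got.p_raw == 1.0


class TestBonferroni:
    def test_arithmetic(self):
        assert bonferroni([0.001], 55)[0] == pytest.approx(0.055)
        assert bonferroni([0.3], 1)[0] == pytest.approx(0.3)
        assert bonferroni([0.5], 10)[0] == 1.0

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    @given(st.floats(1e-6, 1.0), st.integers(1, 50), st.integers(0, 50))
    def test_monotone_in_family_size(self, p, m, extra):
        assert bonferroni([p], m + extra)[0] >= bonferroni([p], m)[0]


class TestSelectCovariates:
    def test_union_deduplicates_across_strata(self):
        df = pd.DataFrame(
            {
                "stratum": ["overall", "sex:female", "overall"],
                "code": ["F329", "F329", "J069"],
                "p_corrected": [0.001, 0.004, 0.9],
                "significant": [True, True, False],
            }
        )
        assert select_covariates(df, 0.05) == ["F329"]

    def test_recovers_planted_code(self, codeset):
        nulls = tuple(CodeSpec(f"R{100 + i}", 0.02, 1.0) for i in range(10))
        cfg = GeneratorConfig(
            n_patients=10_000,
            latent_prevalence=0.05,
            comorbidity_spec=(CodeSpec("F9999", 0.02, 10.0),) + nulls,
            rng_seed=31,
        )
        tables, _ = generate(cfg)
        labels = label_patients(tables.patients, tables.diagnoses, codeset)
        run_cfg = RunConfig()
        analysis = analyze(tables, labels, codeset, run_cfg, strata=[StratumSpec()])
        assert "F9999" in analysis.covariates


class TestAnalyze:
    def test_filter_before_rank_order(self, codeset, run_config):
        """A rare high-probability code must be removed before ranking."""
        # 30 patients: code RARE1 on 5 patients all cases (p_cond 1.0) must
        # not survive a min-support of 20 even though it would top the rank.
        df = pd.DataFrame({"code": ["RARE1", "F329"], "n_code": [5, 25],
                           "n_joint": [5, 10], "p_cond": [1.0, 0.4],
                           "stratum": ["overall"] * 2})
        kept = top_k(support_filter(df, 20), 20)
        assert list(kept["code"]) == ["F329"]

    def test_pipeline_results_schema_and_invariants(self, small_synth, codeset):
        _, tables, _ = small_synth
        labels = label_patients(tables.patients, tables.diagnoses, codeset)
        run_cfg = RunConfig()
        analysis = analyze(tables, labels, codeset, run_cfg)
        r = analysis.results
        assert (r["p_cond"].between(0, 1)).all()
        assert (r["n_joint"] <= r["n_code"]).all()
        assert (r["p_corrected"] >= r["p_raw"] - 1e-15).all()
        assert ((r["p_corrected"] <= run_cfg.alpha) == r["significant"]).all() or (
            r.loc[r["degenerate"].astype(bool)].shape[0] > 0
        )
        assert analysis.n_tests == len(r)
        # Each stratum respects top_k.
        assert r.groupby("stratum").size().max() <= run_cfg.top_k
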