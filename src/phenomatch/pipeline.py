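"""End-to-end orchestration: generate -> label -> comorbidity -> features
-> match -> evaluate, as one reproducible run.

Every stage output is a pure function of (inputs, config, seed).  A
single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence`` with a fixed spawn index per stage, so any
stage can be re-run independently with the same stream.  The manifest
records the config snapshot, per-stage SHA-256 digests of every output
file, timings and warnings; two runs at the same seed produce identical
digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import casedef, comorbidity, evaluation, features, propensity, synth
from .casedef import Codeset
from .datamodel import RunConfig
from .io import Tables, read_tables, write_report, write_tables

logger = logging.getLogger("phenomatch")

#: Fixed spawn indices for the per-stage seed derivation.
STAGE_INDEX = {"generate": 0, "label": 1, "comorbidity": 2, "features": 3,
               "match": 4, "evaluate": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the global seed."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    run_config: RunConfig,
    gen_config: Optional[synth.GeneratorConfig],
    seed: int,
    out_dir,
) -> dict:
    """Run every stage and return the manifest (also written to disk).

    With a generator config the input tables are synthesised; the truth
    table then powers the enrichment evaluation.  Any stage error aborts
    the run, leaving a partial manifest naming the failed stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "config": run_config.to_dict(),
        "stages": {},
        "outputs": {},
        "warnings": [],
    }

    def _record(stage: str, t0: float, paths: dict) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for name, p in paths.items():
            manifest["outputs"][name] = {"path": str(p), "sha256": sha256_file(p)}

    current_stage = "generate"
    try:
        # -- generate ---------------------------------------------------
        t0 = time.time()
        truth = None
        if gen_config is not None:
            gen_config.rng_seed = stage_seed(seed, "generate")
            tables, truth = synth.generate(gen_config)
            paths = write_tables(tables, out_dir)
            paths["truth"] = write_report(truth, out_dir / "truth.csv")
            _record("generate", t0, paths)
            tables = read_tables(
                out_dir / "patients.csv", out_dir / "encounters.csv",
                out_dir / "diagnoses.csv", run_config,
            )
        else:
            raise ValueError("run_all currently requires a generator config "
                             "(no external tables were supplied)")

        # -- label ------------------------------------------------------
        current_stage = "label"
        t0 = time.time()
        run_config.log_effective("label")
        codeset = Codeset.from_file(run_config.resolved_codeset_path())
        labels = casedef.label_patients(tables.patients, tables.diagnoses, codeset)
        p = write_report(casedef.labels_report(labels), out_dir / "case_labels.csv")
        _record("label", t0, {"case_labels": p})

        # -- comorbidity ------------------------------------------------
        current_stage = "comorbidity"
        t0 = time.time()
        analysis = comorbidity.analyze(tables, labels, codeset, run_config)
        p1 = write_report(analysis.results, out_dir / "comorbidity_results.csv")
        p2 = out_dir / "covariates.txt"
        p2.write_text("".join(f"{c}\n" for c in analysis.covariates))
        manifest["n_bonferroni_tests"] = analysis.n_tests
        _record("comorbidity", t0, {"comorbidity_results": p1, "covariates": p2})

        # -- features ---------------------------------------------------
        current_stage = "features"
        t0 = time.time()
        dsm5 = features.Dsm5Map.from_file(run_config.resolved_dsm5_path())
        matrix = features.build_matrix(
            tables, labels, analysis.covariates, codeset, dsm5, run_config
        )
        p = write_report(matrix, out_dir / "features.csv")
        _record("features", t0, {"features": p})

        # -- match ------------------------------------------------------
        current_stage = "match"
        t0 = time.time()
        cols = features.feature_columns(matrix)
        X = matrix[cols]
        y = matrix["is_case"].to_numpy(bool)
        model = propensity.fit_propensity(X, y, l2=run_config.l2)
        scores = pd.Series(model.predict_proba(matrix), index=matrix["patient_id"])
        logits = pd.Series(propensity.logit(scores.to_numpy()), index=scores.index)
        case_ids = matrix.loc[y, "patient_id"].tolist()
        comp_ids = matrix.loc[~y, "patient_id"].tolist()
        result = propensity.match(
            logits, case_ids, comp_ids,
            k=run_config.match_k, caliper=run_config.caliper,
            seed=stage_seed(seed, "match"),
            with_replacement=run_config.match_with_replacement,
        )
        result.balance = propensity.balance_table(X, y, matrix["patient_id"], result.pairs)
        scores_df = pd.DataFrame(
            {"patient_id": scores.index, "propensity": scores.to_numpy(),
             "logit": logits.to_numpy(), "is_case": y}
        )
        p1 = write_report(scores_df, out_dir / "propensity_scores.csv")
        p2 = write_report(result.pairs, out_dir / "matched_pairs.csv")
        p3 = write_report(result.balance, out_dir / "balance.csv")
        _record("match", t0, {"propensity_scores": p1, "matched_pairs": p2, "balance": p3})

        # -- evaluate ---------------------------------------------------
        current_stage = "evaluate"
        t0 = time.time()
        report = build_report(tables, labels, codeset, analysis, matrix, result,
                              truth, case_ids, comp_ids)
        p1 = out_dir / "report.json"
        p1.write_text(json.dumps(_sanitize(report), indent=2, sort_keys=True,
                                 allow_nan=False, default=_json_default) + "\n")
        p2 = out_dir / "report.md"
        p2.write_text(render_report_md(report))
        _record("evaluate", t0, {"report_json": p1, "report_md": p2})
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
        raise

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return manifest


def run_in_memory(
    run_config: RunConfig,
    gen_config: synth.GeneratorConfig,
    seed: int,
    shuffle_scores: bool = False,
) -> dict:
    """Run generate -> label -> comorbidity -> features -> match in memory.

    Returns the stage objects plus the enrichment report; used for
    simulation studies where disk round-trips would dominate.  With
    ``shuffle_scores`` the fitted logits are randomly permuted across
    subjects before matching — the null pipeline in which matching
    carries no information about latent status.
    """
    gen_config.rng_seed = stage_seed(seed, "generate")
    tables, truth = synth.generate(gen_config)
    codeset = Codeset.from_file(run_config.resolved_codeset_path())
    labels = casedef.label_patients(tables.patients, tables.diagnoses, codeset)
    analysis = comorbidity.analyze(tables, labels, codeset, run_config)
    dsm5 = features.Dsm5Map.from_file(run_config.resolved_dsm5_path())
    matrix = features.build_matrix(
        tables, labels, analysis.covariates, codeset, dsm5, run_config
    )
    cols = features.feature_columns(matrix)
    y = matrix["is_case"].to_numpy(bool)
    model = propensity.fit_propensity(matrix[cols], y, l2=run_config.l2)
    scores = pd.Series(model.predict_proba(matrix), index=matrix["patient_id"])
    logits = pd.Series(propensity.logit(scores.to_numpy()), index=scores.index)
    if shuffle_scores:
        rng = np.random.default_rng(stage_seed(seed, "evaluate"))
        logits = pd.Series(rng.permutation(logits.to_numpy()), index=logits.index)
    case_ids = matrix.loc[y, "patient_id"].tolist()
    comp_ids = matrix.loc[~y, "patient_id"].tolist()
    result = propensity.match(
        logits, case_ids, comp_ids, k=run_config.match_k,
        caliper=run_config.caliper, seed=stage_seed(seed, "match"),
        with_replacement=run_config.match_with_replacement,
    )
    enrichment = evaluation.enrichment_report(result.pairs, comp_ids, truth)
    return {
        "tables": tables,
        "truth": truth,
        "labels": labels,
        "analysis": analysis,
        "matrix": matrix,
        "model": model,
        "scores": scores,
        "match": result,
        "case_ids": case_ids,
        "comparator_ids": comp_ids,
        "enrichment": enrichment,
    }


def build_report(
    tables: Tables,
    labels: pd.DataFrame,
    codeset: Codeset,
    analysis: comorbidity.ComorbidityAnalysis,
    matrix: pd.DataFrame,
    result: propensity.MatchResult,
    truth: Optional[pd.DataFrame],
    case_ids: list,
    comp_ids: list,
) -> dict:
    """Assemble the evaluation report from in-memory stage outputs."""
    enc_labels = casedef.label_encounters(tables.encounters, tables.diagnoses, codeset)
    n_enc = len(enc_labels)
    n_case_enc = int(enc_labels["is_case"].sum())
    report: dict = {
        "cohort": {
            "n_patients": int(len(tables.patients)),
            "n_encounters": n_enc,
            "n_case_encounters": n_case_enc,
            "encounter_prevalence_pct": evaluation.prevalence(n_case_enc, n_enc),
            "n_case_patients": int(labels["is_case"].sum()),
        },
        "subtype_prevalence_pct": {},
        "comorbidity": {
            "n_tests": analysis.n_tests,
            "n_significant": int(analysis.results["significant"].sum())
            if len(analysis.results) else 0,
            "covariates": analysis.covariates,
        },
    }
    for subtype in ("ideation", "self_harm", "attempt"):
        k = int(enc_labels["subtypes"].map(lambda s: subtype in s).sum())
        report["subtype_prevalence_pct"][subtype] = evaluation.prevalence(k, n_enc)

    matched_comp = list(dict.fromkeys(result.pairs["comparator_id"]))
    report["scores"] = propensity.score_distribution(
        result.scores, case_ids, comp_ids, matched_comp
    )
    bal = result.balance
    if bal is not None and len(bal):
        report["balance"] = {
            "mean_abs_smd_before": float(bal["smd_before"].abs().mean()),
            "mean_abs_smd_after": float(bal["smd_after"].abs().mean()),
        }
    report["n_matched_pairs"] = int(len(result.pairs))
    report["n_unmatched_cases"] = len(result.unmatched_cases)

    report["enrichment"] = evaluation.enrichment_report(result.pairs, comp_ids, truth)
    if truth is not None:
        report["truth_summary"] = synth.truth_summary(truth, tables.diagnoses, codeset)
        recall = evaluation.latent_recall(result.pairs, comp_ids, truth)
        report["latent_recall_in_matched"] = recall
    return report


def render_report_md(report: dict) -> str:
    """Small human-readable rendering of the report dictionary."""
    c = report["cohort"]
    lines = [
        "# Pipeline report",
        "",
        f"- Patients: {c['n_patients']}, encounters: {c['n_encounters']}",
        f"- Case encounters: {c['n_case_encounters']} "
        f"({c['encounter_prevalence_pct']}%); case patients: {c['n_case_patients']}",
        "- Subtype prevalence (% of encounters): "
        + ", ".join(f"{k} {v}%" for k, v in report["subtype_prevalence_pct"].items()),
        f"- Comorbidity tests: {report['comorbidity']['n_tests']}; "
        f"significant: {report['comorbidity']['n_significant']}",
        f"- Covariates: {', '.join(report['comorbidity']['covariates']) or '(none)'}",
        f"- Matched pairs: {report['n_matched_pairs']}; "
        f"unmatched cases: {report['n_unmatched_cases']}",
    ]
    if "balance" in report:
        b = report["balance"]
        lines.append(
            f"- Mean |SMD| before {b['mean_abs_smd_before']:.3f} "
            f"-> after {b['mean_abs_smd_after']:.3f}"
        )
    e = report.get("enrichment", {})
    if e.get("available"):
        if e.get("degenerate"):
            lines.append("- Enrichment: undefined (no latent uncoded comparators)")
        else:
            lines.append(
                f"- Latent prevalence among matched comparators "
                f"{e['prev_matched']:.4f} vs all comparators {e['prev_all']:.4f} "
                f"(ratio {e['enrichment_ratio']:.2f}, p={e['p']:.3g})"
            )
    return "\n".join(lines) + "\n"


def _sanitize(obj):
    """Recursively replace non-finite floats with None for strict JSON."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    return obj


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
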