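"""End-to-end orchestration: generate -> process -> code -> model -> validate.

Stage order mirrors the split-sample design: questionnaire codes from the
second administration (FFQ2) drive variable selection (items must be
significant in both administrations), empirical weights are fitted on the
development half and scored on the validation half, and the FFQ2-all
weights are additionally replayed against the first administration (FFQ1)
as an internal replication.  All outputs are CSV/JSON plus a manifest with
seeds, row counts and checksums; identical config and seeds reproduce
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import PipelineConfig
from .errors import DegenerateDataError
from .ffq import assign_quartiles
from .modeling import (PredictionEquation, derive_weights, per_item_trend,
                       select_variables, stepwise_select)
from .synthetic import BEHAVIOR_ITEMS, FOOD_GROUPS, generate_cohort, write_cohort
from .urine import daily_values, summarize_excretion
from .validation import balanced_split, compare_approaches, predict_frame

log = logging.getLogger("saltscore")

CHARACTERISTIC_COLS = ["sex", "age", "bmi", "alcohol", "smoker", "htn_med"]
QUARTILE_COLS = [f"{g}_q" for g in FOOD_GROUPS]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _analysis_frame(ffq: pd.DataFrame, instrument: str, participants: pd.DataFrame,
                    summary: pd.DataFrame) -> pd.DataFrame:
    """Per-person modeling table: codes + characteristics + outcomes."""
    codes = ffq[ffq["instrument"] == instrument]
    chars = participants[["participant_id", *CHARACTERISTIC_COLS]]
    merged = codes.merge(chars, on="participant_id", how="inner")
    outcomes = summary[summary["included"]][
        ["participant_id", "na_mg_per_day", "k_mg_per_day", "nak_mol", "n_complete_days"]
    ]
    return merged.merge(outcomes, on="participant_id", how="inner")


def apply_equations(frame: pd.DataFrame, urine_days_complete: pd.DataFrame,
                    equations: Mapping[str, Mapping[str, PredictionEquation]],
                    config: PipelineConfig) -> list[dict]:
    """Score equations on a coded frame and report stratified correlations."""
    return compare_approaches(
        frame, urine_days_complete, equations,
        deattenuate_n=config.deattenuate_n, fixed_n=config.fixed_n_collections,
        energy_method=config.energy_adjust_method, use_pearson=config.use_pearson,
    )


def replicate_ffq1(frame_ffq1: pd.DataFrame, urine_days_complete: pd.DataFrame,
                   equations_from_ffq2: Mapping[str, Mapping[str, PredictionEquation]],
                   config: PipelineConfig) -> list[dict]:
    """Apply FFQ2-derived weights to the FFQ1 responses of the same people."""
    if frame_ffq1.empty:
        raise DegenerateDataError("FFQ1 responses are missing")
    return apply_equations(frame_ffq1, urine_days_complete, equations_from_ffq2, config)


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Execute all stages; returns (and optionally writes) the run manifest."""
    t0 = time.perf_counter()
    outdir = Path(output_dir or config.output_dir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seeds": {"cohort": config.cohort.seed, "split": config.effective_split_seed},
        "stages": {},
        "status": "ok",
    }

    def record(stage: str, files: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(p) for k, p in files.items()},
            "checksums": {k: _sha256(p) for k, p in files.items()},
            "row_counts": counts,
        }
        log.info("stage %-10s done (%.2fs)", stage, time.perf_counter() - t0)

    # -- generate ----------------------------------------------------------
    cohort = generate_cohort(config.cohort)
    paths = write_cohort(cohort, outdir)
    record("generate", {k: Path(v) for k, v in paths.items()},
           {"participants": len(cohort.participants),
            "urine_days": len(cohort.urine_days), "ffq": len(cohort.ffq)})

    # -- process urine -----------------------------------------------------
    summary, exclusions = summarize_excretion(cohort.urine_days)
    p_sum = outdir / "excretion_summary.csv"
    summary.to_csv(p_sum, index=False)
    for e in exclusions:
        log.warning("excluded participant %(participant_id)s: %(reason)s", e)
    record("process", {"excretion_summary": p_sum},
           {"included": int(summary["included"].sum()),
            "excluded": int((~summary["included"]).sum())})

    frame2 = _analysis_frame(cohort.ffq, "FFQ2", cohort.participants, summary)
    frame1 = _analysis_frame(cohort.ffq, "FFQ1", cohort.participants, summary)

    # -- stepwise screen of potassium-source food groups (FFQ2, Na/K) ------
    step = stepwise_select(frame2[QUARTILE_COLS], frame2["nak_mol"].to_numpy(),
                           entry=config.stepwise_entry, stay=config.stepwise_stay)
    manifest["stepwise_selected_groups"] = step.selected

    # -- per-item trends and dual-administration selection -----------------
    candidates = {"sodium_mg": list(BEHAVIOR_ITEMS),
                  "nak_mol": list(BEHAVIOR_ITEMS) + step.selected}
    trend_frames = []
    selections: dict[str, list[str]] = {}
    for outcome, items in candidates.items():
        res1 = [per_item_trend(frame1, item, outcome) for item in items]
        res2 = [per_item_trend(frame2, item, outcome) for item in items]
        for instrument, res in (("FFQ1", res1), ("FFQ2", res2)):
            trend_frames.append(pd.DataFrame(
                [{"item": r.item, "slope": r.slope, "se": r.se, "p_trend": r.p_trend,
                  "n": r.n, "instrument": instrument, "outcome": outcome}
                 for r in res]))
        selections[outcome] = select_variables(res1, res2, alpha=config.alpha)
    trends = pd.concat(trend_frames, ignore_index=True)
    p_trends = outdir / "table2_trends.csv"
    trends.to_csv(p_trends, index=False)
    record("trends", {"table2_trends": p_trends}, {"rows": len(trends)})
    manifest["selected_items"] = selections

    empty = [o for o, items in selections.items() if not items]
    if empty:
        manifest["status"] = "halted:no_significant_items:" + ",".join(sorted(empty))
        log.warning("no items significant in both administrations for %s; "
                    "halting before weight derivation", empty)
        _write_manifest(manifest, outdir)
        return manifest

    # -- balanced split ----------------------------------------------------
    strata = frame2[["participant_id", "sex", "taste_preference"]].copy()
    strata["top_na_quartile"] = (assign_quartiles(frame2["fci_na_mg"].to_numpy()) == 4).astype(int)
    split = balanced_split(strata, config.effective_split_seed)
    p_split = outdir / "split.csv"
    split.to_csv(p_split, index=False)
    dev_ids = set(split.loc[split["group"] == "development", "participant_id"])
    record("split", {"split": p_split},
           {"development": len(dev_ids), "validation": len(split) - len(dev_ids)})

    # -- empirical weights -------------------------------------------------
    dev2 = frame2[frame2["participant_id"].isin(dev_ids)]
    variants = ["behavior_only"] + (
        ["with_characteristics"] if config.include_characteristics else [])
    weights: dict[str, dict[str, dict[str, PredictionEquation]]] = {}
    for sample, data in (("all", frame2), ("development", dev2)):
        weights[sample] = {}
        for outcome_key, outcome in (("sodium", "sodium_mg"), ("nak", "nak_mol")):
            weights[sample][outcome_key] = {
                v: derive_weights(data, selections[outcome], outcome,
                                  include_characteristics=(v == "with_characteristics"))
                for v in variants
            }
    p_weights = outdir / "table3_weights.json"
    with open(p_weights, "w") as fh:
        json.dump({s: {o: {v: {"outcome": eq.outcome, "intercept": eq.intercept,
                               "coefficients": eq.coefficients,
                               "includes_characteristics": eq.includes_characteristics}
                           for v, eq in by_v.items()}
                       for o, by_v in by_o.items()}
                   for s, by_o in weights.items()}, fh, indent=2)
    record("weights", {"table3_weights": p_weights},
           {"equations": sum(len(v) for s in weights.values() for v in s.values())})

    # -- validation --------------------------------------------------------
    val_frame = frame2[~frame2["participant_id"].isin(dev_ids)]
    if config.exclude_htn_med:
        val_frame = val_frame[val_frame["htn_med"] == 0]
    days = daily_values(cohort.urine_days)
    days_complete = days[days["missed_voids"] == 0]
    report = apply_equations(val_frame, days_complete, weights["development"], config)
    p_report = outdir / "table4_report.json"
    with open(p_report, "w") as fh:
        json.dump(report, fh, indent=2)

    ba_rows = []
    for outcome_key, meas_col in (("sodium", "na_mg_per_day"), ("nak", "nak_mol")):
        for variant in variants:
            eq = weights["development"][outcome_key][variant]
            est = predict_frame(eq, val_frame)
            ba_rows.append(pd.DataFrame({
                "participant_id": val_frame["participant_id"].to_numpy(),
                "outcome": outcome_key, "variant": variant,
                "estimate": est, "measured": val_frame[meas_col].to_numpy(),
            }))
    ba = pd.concat(ba_rows, ignore_index=True)
    p_ba = outdir / "bland_altman.csv"
    ba.to_csv(p_ba, index=False)
    record("validate", {"table4_report": p_report, "bland_altman": p_ba},
           {"report_rows": len(report), "ba_rows": len(ba)})

    if config.make_plots:
        from .validation import plot_bland_altman
        for outcome_key, meas_col in (("sodium", "na_mg_per_day"), ("nak", "nak_mol")):
            eq = weights["development"][outcome_key][variants[-1]]
            plot_bland_altman(predict_frame(eq, val_frame),
                              val_frame[meas_col].to_numpy(),
                              outdir / f"bland_altman_{outcome_key}.svg",
                              title=outcome_key)

    # -- FFQ1 replication --------------------------------------------------
    if config.run_ffq1_replication:
        rep1 = replicate_ffq1(frame1, days_complete, weights["all"], config)
        rep2 = apply_equations(frame2, days_complete, weights["all"], config)
        p_rep = outdir / "ffq1_replication.json"
        with open(p_rep, "w") as fh:
            json.dump({"ffq1": rep1, "ffq2": rep2}, fh, indent=2)
        record("replicate", {"ffq1_replication": p_rep},
               {"ffq1_rows": len(rep1), "ffq2_rows": len(rep2)})

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
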