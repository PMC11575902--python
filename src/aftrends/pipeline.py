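"""End-to-end orchestration: simulate -> preprocess -> trends -> discover -> evaluate.

Every artifact is a delimited-text or JSON file stamped with the config hash
and the stage seed, so two runs with the same configuration and seed produce
byte-identical outputs.  Per-stage seeds are derived deterministically from
the global seed and the stage name, which makes stages independently
re-runnable.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery, evaluation, synth, trends
from .config import PipelineConfig
from .timeline import apply_inclusion, classify_af_phenotype, write_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "trends", "discover", "evaluate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_round_floats(v, ndigits) for v in obj.tolist()]
    return obj


def _json_dump(obj: dict, path: Path, stamp: dict) -> None:
    payload = {"_provenance": stamp, **_round_floats(obj)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n",
                    encoding="utf-8")


def _serialize_report(report: dict) -> dict:
    out = {}
    for k, v in report.items():
        if isinstance(v, pd.DataFrame):
            out[k] = v.to_dict(orient="records")
        elif isinstance(v, evaluation.YieldReport):
            out[k] = {
                "regions": {"+".join(sorted(s)): c for s, c in v.regions.items()},
                "total_captured": v.total_captured,
                "trend_exclusive_events": v.trend_exclusive_events,
                "clinical_events": v.clinical_events,
                "percent_increase": v.percent_increase,
                "trend_days_total": v.trend_days_total,
                "trend_days_exclusive": v.trend_days_exclusive,
                "day_exclusivity_pct": v.day_exclusivity_pct,
            }
        elif isinstance(v, dict):
            out[k] = {str(kk): (_serialize_report(vv) if isinstance(vv, dict) else vv)
                      for kk, vv in v.items()}
        else:
            out[k] = v
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis; returns the artifact paths.

    On stage failure a :class:`PipelineError` carrying the stage name is
    raised; artifacts from completed stages are retained on disk.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = lambda stage: {"config_hash": chash, "seed": config.seed,
                           "stage_seed": derive_seed(config.seed, stage)}
    header = lambda stage: (f"aftrends config={chash} seed={config.seed} "
                            f"stage={stage} stage_seed={derive_seed(config.seed, stage)}")
    artifacts: dict[str, Path] = {}

    # --- simulate -----------------------------------------------------------
    sim_cfg = replace(config.simulation, seed=derive_seed(config.seed, "simulate"))
    cohort, truth = synth.simulate_cohort(sim_cfg, config.trends)
    write_cohort(cohort, out / "cohort_daily.csv", out / "cohort_patients.csv",
                 header_comment=header("simulate"))
    truth_frame = truth.as_frame()
    with open(out / "ground_truth.csv", "w", encoding="utf-8") as fh:
        fh.write(f"# {header('simulate')}\n")
        truth_frame.to_csv(fh, index=False)
    artifacts["cohort_daily"] = out / "cohort_daily.csv"
    artifacts["cohort_patients"] = out / "cohort_patients.csv"
    artifacts["ground_truth"] = out / "ground_truth.csv"
    log.info("simulated %d patients", len(cohort))

    # --- preprocess ---------------------------------------------------------
    if not cohort:
        raise PipelineError("preprocess", "empty cohort (n_patients=0?)")
    retained, exclusions = apply_inclusion(cohort)
    if not retained:
        raise PipelineError("preprocess", "no patients satisfy the inclusion criteria")
    with open(out / "exclusions.csv", "w", encoding="utf-8") as fh:
        fh.write(f"# {header('preprocess')}\n")
        exclusions.to_csv(fh, index=False)
    artifacts["exclusions"] = out / "exclusions.csv"
    log.info("retained %d/%d patients", len(retained), len(cohort))

    # --- trends -------------------------------------------------------------
    flags = trends.flag_cohort(retained, config.trends)
    with open(out / "day_flags.csv", "w", encoding="utf-8") as fh:
        fh.write(f"# {header('trends')}\n")
        flags.to_csv(fh, index=False)
    artifacts["day_flags"] = out / "day_flags.csv"

    # --- discover (train split) --------------------------------------------
    try:
        train, holdout = discovery.split_patients(
            retained, config.discovery.train_fraction,
            seed=derive_seed(config.seed, "split"))
        mined = discovery.mine_rules(train, config.trends, config.discovery,
                                     seed=derive_seed(config.seed, "discover"))
    except ValueError as exc:
        raise PipelineError("discover", str(exc)) from exc
    rules_text = f"# {header('discover')}\n" + discovery.rules_to_text(mined["rules"])
    (out / "rules.txt").write_text(rules_text, encoding="utf-8")
    matched = mined["matched"]
    # freeze the matched (D-shaped) rule's thresholds before holdout evaluation
    eval_trends = config.trends
    if matched is not None:
        eval_trends = discovery.rule_to_trend_config(matched, config.trends)
    matched_payload = {
        "comparators": mined["comparators"],
        "matched_rule": None if matched is None else {
            "rule": matched.describe(),
            "selection_frequency": matched.selection_frequency,
            "log_rr": matched.log_rr,
            "patient_pct": matched.patient_pct,
            "day_pct": matched.day_pct,
        },
        "frozen_trend_config": {
            "trend_d_burden_cma_min": eval_trends.trend_d_burden_cma_min,
            "trend_d_activity_cma_max": eval_trends.trend_d_activity_cma_max,
        },
    }
    _json_dump(matched_payload, out / "matched_rule.json", stamp("discover"))
    artifacts["rules"] = out / "rules.txt"
    artifacts["matched_rule"] = out / "matched_rule.json"

    # --- evaluate (holdout) -------------------------------------------------
    eval_cohort = holdout if holdout else retained
    phenotypes = {}
    for tl in eval_cohort:
        try:
            phenotypes[tl.patient_id] = classify_af_phenotype(tl)
        except ValueError:
            phenotypes[tl.patient_id] = "paroxysmal"
    report = evaluation.evaluate_holdout(
        eval_cohort, eval_trends, config.discovery.horizon_days, phenotypes)
    _json_dump(_serialize_report(report), out / "report.json", stamp("evaluate"))
    artifacts["report"] = out / "report.json"
    return {k: str(v) for k, v in artifacts.items()}


def render_report(report_path: str | Path) -> str:
    """Human-readable summary of a report.json artifact."""
    data = json.loads(Path(report_path).read_text(encoding="utf-8"))
    lines = [f"aftrends report ({report_path})",
             f"provenance: {data.get('_provenance')}"]
    fu = data.get("follow_up", {})
    lines.append(f"patients: {fu.get('n_patients')}  patient-days: "
                 f"{fu.get('total_patient_days')}  events: {fu.get('n_events')}")
    rrs = data.get("state_rate_ratios", {})
    for state in ("B", "C", "D"):
        if state in rrs:
            r = rrs[state]
            lines.append(f"RR {state} vs A: {r['rr']:.2f} "
                         f"[{r['ci_low']:.2f}, {r['ci_high']:.2f}]")
    auroc = data.get("auroc", {})
    if "clinical" in auroc:
        lines.append(f"AUROC clinical: {auroc['clinical']['auc']:.3f} -> "
                     f"with trend: {auroc['with_trend']['auc']:.3f} "
                     f"(+{auroc['relative_increase_pct']:.1f}% relative)")
    y = data.get("yield", {})
    if y:
        lines.append(f"trend-exclusive events: {y.get('trend_exclusive_events')} "
                     f"(+{y.get('percent_increase', float('nan')):.1f}% over clinical)")
    return "\n".join(lines)
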