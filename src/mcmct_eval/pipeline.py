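"""End-to-end orchestration: simulate -> emulate -> evaluate -> stability ->
samplesize -> report.

One YAML run config describes the farm, the simulation grid, the error model
and the evaluation settings.  All randomness flows from a single master seed:
stage ``s`` uses ``numpy.random.SeedSequence([master_seed, STAGE_CODE[s]])``,
so stages can be rerun independently yet reproduce byte-identical artifacts.
Every run writes a ``manifest.json`` recording the seed, a hash of the
config, and each artifact produced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .barn_sim import BehaviorProfile, SimConfig, simulate_herd
from .farm_config import validate_farm_config
from .hybrid_eval import (
    TASKS,
    DetectionCounts,
    classify_pairs,
    compute_metrics,
    evaluate_detection_day,
    percent,
    sample_size,
)
from .stability import fit_hour_day_model, hourly_proportions, tukey_pairwise
from .system_emulator import ErrorModel, emulate, is_ghost_id, uniform_confusion

__all__ = [
    "STAGES",
    "PipelineError",
    "RunConfig",
    "load_run_config",
    "stage_rng",
    "observation_pairs",
    "daily_detection_evaluation",
    "render_report",
    "run_pipeline",
]

STAGES = ("simulate", "emulate", "evaluate", "stability", "samplesize", "report")
_STAGE_CODE = {s: i for i, s in enumerate(STAGES)}

#: artifacts each stage needs (by file name) and produces
_STAGE_INPUTS = {
    "simulate": (),
    "emulate": ("truth.csv", "visits.csv"),
    "evaluate": ("truth.csv", "visits.csv", "records.csv", "snapshots.csv"),
    "stability": ("visits.csv", "snapshots.csv"),
    "samplesize": (),
    "report": ("evaluation_metrics.csv",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """A pipeline run: config file, output directory, master seed, stages."""

    config_path: str
    outdir: str
    seed: Optional[int] = None  # overrides the seed in the config file
    stages: Sequence[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stage(s): {unknown}; valid stages are {STAGES}")
        # preserve pipeline order regardless of how stages were listed
        self.stages = [s for s in STAGES if s in set(self.stages)]


def load_run_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise PipelineError(f"run config {path} did not parse to a mapping")
    if "farm" not in raw:
        raise PipelineError("run config must contain a 'farm' section")
    return dict(raw)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream split from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), _STAGE_CODE[stage]]))


def _build_sim_config(cfg: Mapping, seed: int) -> SimConfig:
    sim_raw = dict(cfg.get("sim", {}))
    profile_raw = dict(sim_raw.pop("profile", {}) or {})
    profile = BehaviorProfile(**profile_raw)
    sim_raw.pop("seed", None)
    return SimConfig(seed=seed, profile=profile, **sim_raw)


def _build_error_model(cfg: Mapping) -> ErrorModel:
    raw = dict(cfg.get("error_model", {}) or {})
    accuracy = raw.pop("activity_accuracy", None)
    known = {f.name for f in dc_fields(ErrorModel)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown error_model fields: {sorted(unknown)}")
    em = ErrorModel(**raw)
    if accuracy is not None:
        em.activity_confusion = uniform_confusion(float(accuracy))
    em.validate()
    return em


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------

def observation_pairs(
    truth: pd.DataFrame,
    records: pd.DataFrame,
    days: Optional[Sequence[int]] = None,
    rng: Optional[np.random.Generator] = None,
    n_samples: Optional[int] = None,
) -> pd.DataFrame:
    """Gold-standard observation pairs from truth and emulated records.

    Emulates the on-farm observer protocol: each truth event on the selected
    day(s) is paired with the system's concurrent output for that physical
    cow (``records.source_id`` provides the physical-track bookkeeping);
    ghost records become present=False pairs.  Optionally subsamples
    ``n_samples`` pairs with ``rng``.
    """
    if "source_id" not in records.columns:
        raise ValueError("records need a 'source_id' column to build observation pairs")
    if days is not None:
        truth = truth[truth["day"].isin(days)]
        records = records[records["day"].isin(days)]

    ghost_mask = records["source_id"].astype(str).map(is_ghost_id)
    real = records.loc[~ghost_mask]

    gold = pd.DataFrame(
        {
            "day": truth["day"].to_numpy(),
            "tick_minute": truth["tick_minute"].to_numpy(),
            "gold_id": truth["cow_id"].astype(str).to_numpy(),
            "gold_activity": truth["activity"].astype(str).to_numpy(),
            "gold_zone": truth["zone"].astype(str).to_numpy(),
        }
    )
    sys_out = pd.DataFrame(
        {
            "day": real["day"].to_numpy(),
            "tick_minute": real["tick_minute"].to_numpy(),
            "gold_id": real["source_id"].astype(str).to_numpy(),
            "sys_id": real["assigned_id"].astype(str).to_numpy(),
            "sys_activity": real["activity"].astype(str).to_numpy(),
            "sys_zone": real["zone"].astype(str).to_numpy(),
        }
    )
    merged = gold.merge(sys_out, on=["day", "tick_minute", "gold_id"], how="left")
    merged["present"] = True
    merged["detected"] = merged["sys_id"].notna()

    ghost = records.loc[ghost_mask]
    ghost_pairs = pd.DataFrame(
        {
            "present": False,
            "gold_id": None,
            "gold_activity": None,
            "gold_zone": None,
            "detected": True,
            "sys_id": ghost["assigned_id"].astype(str).to_numpy(),
            "sys_activity": ghost["activity"].astype(str).to_numpy(),
            "sys_zone": ghost["zone"].astype(str).to_numpy(),
        }
    )
    cols = [
        "present",
        "gold_id",
        "gold_activity",
        "gold_zone",
        "detected",
        "sys_id",
        "sys_activity",
        "sys_zone",
    ]
    pairs = pd.concat([merged[cols], ghost_pairs[cols]], ignore_index=True)
    if n_samples is not None and n_samples < len(pairs):
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.choice(len(pairs), size=int(n_samples), replace=False)
        pairs = pairs.iloc[np.sort(idx)].reset_index(drop=True)
    return pairs


def daily_detection_evaluation(
    visits: pd.DataFrame, snaps: pd.DataFrame, herd_registry
) -> tuple[pd.DataFrame, DetectionCounts]:
    """Per-day detection cells (AMS list vs daily detected-ID list) and their sum."""
    registry = set(map(str, herd_registry))
    ams_by_day = visits.groupby("day")["cow_id"].apply(lambda s: set(map(str, s)))
    det_by_day = snaps.groupby("day")["detected_id"].apply(lambda s: set(map(str, s)))
    rows = []
    for day in sorted(ams_by_day.index):
        counts = evaluate_detection_day(
            ams_by_day[day], det_by_day.get(day, set()), registry
        )
        rows.append(
            {"day": int(day), "tp_d": counts.tp_d, "fn_d": counts.fn_d, "fp_d": counts.fp_d}
        )
    per_day = pd.DataFrame(rows, columns=["day", "tp_d", "fn_d", "fp_d"])
    total = DetectionCounts(
        tp_d=int(per_day["tp_d"].sum()),
        fn_d=int(per_day["fn_d"].sum()),
        fp_d=int(per_day["fp_d"].sum()),
    )
    return per_day, total


def _fmt(value) -> str:
    return "NA" if value is None else f"{value:.2f}"


def render_report(metric_rows: Sequence[Mapping], stability_summary: Optional[str] = None) -> str:
    """Human-readable report table.

    ``metric_rows``: mappings with keys ``task, farm_id, tp_pct, fn_pct,
    fp_pct, recall_pct, precision_pct, f1_pct`` (percent units).  Values are
    printed with 2 decimals in the column order TP, FN, FP, recall,
    precision, F1.
    """
    header = (
        f"{'Task':<16}{'Farm':<6}{'TP (%)':>8}{'FN (%)':>8}{'FP (%)':>8}"
        f"{'Recall':>8}{'Precision':>11}{'F1-score':>10}"
    )
    lines = [header, "-" * len(header)]
    for row in metric_rows:
        lines.append(
            f"{row['task']:<16}{row['farm_id']:<6}"
            f"{_fmt(row['tp_pct']):>8}{_fmt(row['fn_pct']):>8}{_fmt(row['fp_pct']):>8}"
            f"{_fmt(row['recall_pct']):>8}{_fmt(row['precision_pct']):>11}{_fmt(row['f1_pct']):>10}"
        )
    report = "\n".join(lines)
    if stability_summary:
        report += "\n\nDetection stability\n-------------------\n" + stability_summary
    return report + "\n"


# ---------------------------------------------------------------------------
# Stage execution
# ---------------------------------------------------------------------------

def _require_artifacts(outdir: Path, stage: str, produced: set) -> None:
    for name in _STAGE_INPUTS[stage]:
        if name in produced or (outdir / name).exists():
            continue
        raise PipelineError(
            f"stage '{stage}' requires artifact '{name}' which is neither on disk "
            f"in {outdir} nor produced earlier in this run"
        )


def run_pipeline(rc: RunConfig) -> dict:
    """Execute the requested stages in pipeline order; returns the manifest."""
    cfg = load_run_config(rc.config_path)
    farm = validate_farm_config(cfg["farm"])
    seed = rc.seed if rc.seed is not None else int(cfg.get("seed", 0))
    outdir = Path(rc.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    config_hash = hashlib.sha256(Path(rc.config_path).read_bytes()).hexdigest()
    manifest = {
        "seed": seed,
        "config_sha256": config_hash,
        "farm_id": farm.farm_id,
        "stages": list(rc.stages),
        "files": {},
    }
    produced: set = set()

    def emit(name: str, writer, obj) -> None:
        path = outdir / name
        writer(obj, path)
        manifest["files"][name] = str(path)
        produced.add(name)

    eval_cfg = dict(cfg.get("evaluation", {}) or {})

    for stage in rc.stages:
        _require_artifacts(outdir, stage, produced)

        if stage == "simulate":
            sim = _build_sim_config(cfg, seed)
            truth, visits = simulate_herd(farm, sim, rng=stage_rng(seed, "simulate"))
            emit("truth.csv", mio.write_truth_events, truth)
            emit("visits.csv", mio.write_ams_visits, visits)

        elif stage == "emulate":
            truth = mio.read_truth_events(outdir / "truth.csv")
            visits = mio.read_ams_visits(outdir / "visits.csv")
            em = _build_error_model(cfg)
            records, snaps = emulate(truth, visits, em, stage_rng(seed, "emulate"))
            emit("records.csv", mio.write_system_records, records)
            emit("snapshots.csv", mio.write_snapshots, snaps)

        elif stage == "evaluate":
            truth = mio.read_truth_events(outdir / "truth.csv")
            visits = mio.read_ams_visits(outdir / "visits.csv")
            records = mio.read_system_records(outdir / "records.csv")
            snaps = mio.read_snapshots(outdir / "snapshots.csv")

            _, det_total = daily_detection_evaluation(
                visits, snaps, truth["cow_id"].unique()
            )
            det_metrics = compute_metrics(det_total)
            rows = [
                {
                    "task": "detection",
                    "farm_id": farm.farm_id,
                    "tp_pct": percent(det_total.tp_d / max(det_total.tp_d + det_total.fn_d, 1)),
                    "fn_pct": percent(det_total.fn_d / max(det_total.tp_d + det_total.fn_d, 1)),
                    "fp_pct": percent(det_total.fp_d / max(det_total.tp_d + det_total.fn_d, 1)),
                    "recall_pct": percent(det_metrics.recall),
                    "precision_pct": percent(det_metrics.precision),
                    "f1_pct": percent(det_metrics.f1),
                }
            ]
            pairs = observation_pairs(
                truth,
                records,
                days=eval_cfg.get("days"),
                rng=stage_rng(seed, "evaluate"),
                n_samples=eval_cfg.get("n_samples"),
            )
            n_present = int(pairs["present"].astype(bool).sum())
            for task in TASKS:
                counts = classify_pairs(
                    pairs, task, require_correct_id=bool(eval_cfg.get("require_correct_id", False))
                )
                metrics = compute_metrics(counts)
                rows.append(
                    {
                        "task": task,
                        "farm_id": farm.farm_id,
                        "tp_pct": percent(counts.tp / max(n_present, 1)),
                        "fn_pct": percent(counts.fn / max(n_present, 1)),
                        "fp_pct": percent(counts.fp / max(n_present, 1)),
                        "recall_pct": percent(metrics.recall),
                        "precision_pct": percent(metrics.precision),
                        "f1_pct": percent(metrics.f1),
                    }
                )
            emit("evaluation_metrics.csv", mio.write_table, pd.DataFrame(rows))
            kv = {
                f"{row['task']}_{m}": row[f"{m}_pct"]
                for row in rows
                for m in ("recall", "precision", "f1")
            }
            emit("metrics.txt", mio.write_key_values, kv)

        elif stage == "stability":
            visits = mio.read_ams_visits(outdir / "visits.csv")
            snaps = mio.read_snapshots(outdir / "snapshots.csv")
            ams_counts = visits.groupby("day")["cow_id"].nunique().to_dict()
            tick = int(cfg.get("sim", {}).get("tick", 5))
            hourly = hourly_proportions(snaps, ams_counts, tick=tick, farm_id=farm.farm_id)
            emit("hourly.csv", mio.write_table, hourly)
            fit = fit_hour_day_model(hourly)
            pairwise = tukey_pairwise(fit, alpha=float(eval_cfg.get("alpha", 0.01)))
            emit("pairwise.csv", mio.write_table, pairwise)
            summary = {
                "n_days": fit.n_days,
                "grand_mean_pct": percent(fit.grand_mean),
                "se_emm_pct": percent(fit.se_emm),
                "sigma2_day": fit.sigma2_day,
                "sigma2_resid": fit.sigma2_resid,
                "df_resid": fit.df_resid,
                "f_hour": fit.f_hour,
                "p_hour": fit.p_hour,
                "min_hour": int(fit.hours[int(np.argmin(fit.emm))]),
                "min_emm_pct": percent(float(fit.emm.min())),
                "max_hour": int(fit.hours[int(np.argmax(fit.emm))]),
                "max_emm_pct": percent(float(fit.emm.max())),
                "n_significant_pairs": int(pairwise["significant"].sum()),
            }
            emit("stability_fit.txt", mio.write_key_values, summary)

        elif stage == "samplesize":
            specs = cfg.get("samplesize") or [
                {"p": 0.5, "margin": 0.05, "confidence": 0.95, "population": farm.n_cows}
            ]
            kv = {}
            for i, spec in enumerate(specs):
                n = sample_size(
                    float(spec["p"]),
                    float(spec["margin"]),
                    float(spec.get("confidence", 0.95)),
                    spec.get("population"),
                )
                label = spec.get("label", f"spec{i + 1}")
                kv[f"{label}_n"] = n
            emit("samplesize.txt", mio.write_key_values, kv)

        elif stage == "report":
            metrics_df = mio.read_table(outdir / "evaluation_metrics.csv")
            rows = metrics_df.where(pd.notna(metrics_df), None).to_dict("records")
            stability_summary = None
            fit_path = outdir / "stability_fit.txt"
            if fit_path.exists():
                kv = mio.read_key_values(fit_path)
                stability_summary = "\n".join(f"{k} = {v}" for k, v in kv.items())
            emit(
                "report.txt",
                lambda text, path: Path(path).write_text(text, encoding="utf-8"),
                render_report(rows, stability_summary),
            )

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    manifest["files"]["manifest.json"] = str(manifest_path)
    return manifest
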