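"""Pipeline orchestration: from inputs (or simulation) to the report bundle.

``run_pipeline`` executes the full analysis and writes seven artifacts to
the output directory:

1. ``features.csv``        — per scan/side shape-feature values (long form)
2. ``asymmetry.csv``       — per scan/metric asymmetry indices
3. ``limits.json``         — normative AI limits plus discrimination
                             metrics (sensitivity/specificity/F1 at 3 SD,
                             AUC of the absolute AI)
4. ``classification.csv``  — per-scan flags at each limit level
5. ``ranking.csv``         — shape-feature importance ranking
6. ``robustness.csv``      — MAPE and ICC(2,1) per metric over re-scan
                             sessions
7. ``report.svg/.png`` (+ ``report_coordinates.csv``) — the quantitative
                             left-vs-right report

plus ``run_log.json`` recording the config hash, seed and library versions.
Any stage failure aborts with an error naming the stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import (METRIC_DIRECTIONS, asymmetry_index, binary_metrics,
                        classify_by_asymmetry, fit_normative_limits, roc_auc)
from .io import (ScanRecord, UNILATERAL_HS_GROUPS, extract_structure_masks,
                 read_cohort_table, read_label_volume)
from .ranking import rank_shape_features
from .report import ReportSpec, render_report
from .robustness import build_sessions, icc_2_1, mape
from .shape import FEATURE_NAMES, compute_shape_features
from .synthetic import CohortConfig, generate_measurement_cohort

__all__ = ["PipelineError", "load_config", "run_pipeline"]

_BIOMARKER_METRICS = ("volume", "surface_to_volume_ratio")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config file must contain a mapping")
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapper
    return deco


@_stage("load")
def _load_records(config: dict, seed: int) -> List[ScanRecord]:
    if "simulate" in config:
        overrides = dict(config.get("simulate") or {})
        cohort_cfg = CohortConfig(**overrides)
        return generate_measurement_cohort(cohort_cfg, seed=seed)
    if "inputs" not in config:
        raise PipelineError("config missing key: need 'simulate' or 'inputs'")
    inputs = config["inputs"]
    if "cohort_csv" not in inputs:
        raise PipelineError("config missing key 'inputs.cohort_csv'")
    records = read_cohort_table(inputs["cohort_csv"])
    nifti_dir = inputs.get("nifti_dir")
    if nifti_dir:
        dialect = inputs.get("dialect", "freesurfer-aseg")
        for rec in records:
            path = Path(nifti_dir) / f"{rec.scan_id}.nii.gz"
            if not path.exists():
                path = Path(nifti_dir) / f"{rec.scan_id}.nii"
            if not path.exists():
                continue
            vol = read_label_volume(path)
            left, right = extract_structure_masks(vol, dialect)
            feats_l = compute_shape_features(left).as_dict()
            feats_r = compute_shape_features(right).as_dict()
            for name in FEATURE_NAMES:
                rec.measures[name] = (feats_l[name], feats_r[name])
            rec.measures["volume"] = (feats_l["voxel_volume"],
                                      feats_r["voxel_volume"])
    return records


@_stage("features")
def _write_features(records, outdir: Path) -> None:
    rows = []
    for r in records:
        for metric, (lh, rh) in sorted(r.measures.items()):
            rows.append({"scan_id": r.scan_id, "metric": metric,
                         "lh": lh, "rh": rh})
    pd.DataFrame(rows).to_csv(outdir / "features.csv", index=False)


@_stage("asymmetry")
def _write_asymmetry(records, outdir: Path) -> pd.DataFrame:
    rows = []
    for r in records:
        for metric, (lh, rh) in sorted(r.measures.items()):
            rows.append({"scan_id": r.scan_id, "subject_id": r.subject_id,
                         "group": r.group, "metric": metric,
                         "ai": asymmetry_index(lh, rh)})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "asymmetry.csv", index=False)
    return df


@_stage("biomarker")
def _biomarker(records, ai_df: pd.DataFrame, outdir: Path) -> Dict:
    limits_out: Dict[str, Dict] = {}
    class_rows = []
    for metric in _BIOMARKER_METRICS:
        sub = ai_df[ai_df["metric"] == metric]
        hc_ai = sub.loc[sub["group"] == "HC", "ai"].to_numpy()
        limits = fit_normative_limits(hc_ai, metric=metric)
        limits_out[metric] = {
            "hc_mean_ai": limits.hc_mean_ai, "hc_sd_ai": limits.hc_sd_ai,
            "n_hc": limits.n_hc,
            "thresholds": {k: list(v) for k, v in limits.thresholds.items()},
        }
        preds_3sd, groups = [], []
        for _, row in sub.iterrows():
            for level in ("2SD", "3SD"):
                label = classify_by_asymmetry(row["ai"], limits, level=level)
                class_rows.append({"scan_id": row["scan_id"], "metric": metric,
                                   "level": level, "label": label})
                if level == "3SD":
                    preds_3sd.append(label)
                    groups.append(row["group"])
        outcome = binary_metrics(preds_3sd, groups)
        contrast = sub[sub["group"].isin(list(UNILATERAL_HS_GROUPS) + ["EPI-other"])]
        auc = roc_auc(contrast["ai"].abs().to_numpy(),
                      contrast["group"].isin(UNILATERAL_HS_GROUPS).astype(int).to_numpy())
        limits_out[metric]["discrimination_3SD"] = {
            "sensitivity": outcome.sensitivity, "specificity": outcome.specificity,
            "f1": outcome.f1, "n": outcome.n, "auc_abs_ai": auc,
        }
    with open(outdir / "limits.json", "w") as fh:
        json.dump(limits_out, fh, indent=2, sort_keys=True)
    pd.DataFrame(class_rows).to_csv(outdir / "classification.csv", index=False)
    return limits_out


@_stage("ranking")
def _write_ranking(records, seed: int, outdir: Path) -> None:
    ranking = rank_shape_features(records, seed=seed)
    pd.DataFrame({
        "feature": ranking.features,
        "mean_importance": ranking.importances,
        "rank": ranking.ranks,
    }).sort_values("rank").to_csv(outdir / "ranking.csv", index=False)


@_stage("robustness")
def _write_robustness(records, outdir: Path) -> None:
    sessions = build_sessions(records)
    rows = []
    for metric in _BIOMARKER_METRICS:
        for side, idx in (("lh", 0), ("rh", 1)):
            values = {r.scan_id: r.measures[metric][idx] for r in records}
            rows.append({
                "metric": f"{side}_{metric}",
                "mape_percent": mape(sessions, values),
                "icc_2_1": icc_2_1(sessions, values),
                "n_sessions": len(sessions),
            })
    pd.DataFrame(rows).to_csv(outdir / "robustness.csv", index=False)


@_stage("report")
def _write_report(records, ai_df, metric: str, report_cfg: dict,
                  outdir: Path) -> None:
    sub = ai_df[ai_df["metric"] == metric]
    hc_ai = sub.loc[sub["group"] == "HC", "ai"].to_numpy()
    limits = fit_normative_limits(hc_ai, metric=metric)
    spec = ReportSpec(
        metric=metric,
        levels=tuple(report_cfg.get("levels", ("2SD", "3SD"))),
        highlight_scan_ids=tuple(report_cfg.get("highlight", ())),
        image_path=str(outdir / "report.svg"),
        coordinates_path=str(outdir / "report_coordinates.csv"),
    )
    render_report(records, limits, spec)


def run_pipeline(config, outdir=None, seed: Optional[int] = None) -> Dict:
    """Run all stages; ``config`` is a dict or a YAML file path.

    Returns a summary dict with the output paths and headline numbers.
    ``seed`` overrides ``config['seed']`` when given.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    outdir = Path(outdir if outdir is not None else config.get("outdir", "hippoasym-out"))
    outdir.mkdir(parents=True, exist_ok=True)

    records = _load_records(config, seed)
    _write_features(records, outdir)
    ai_df = _write_asymmetry(records, outdir)
    limits = _biomarker(records, ai_df, outdir)
    _write_ranking(records, seed, outdir)
    _write_robustness(records, outdir)
    metric = config.get("metric", "surface_to_volume_ratio")
    _write_report(records, ai_df, metric, config.get("report", {}), outdir)

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    log = {
        "config_sha256": cfg_hash,
        "seed": seed,
        "n_scans": len(records),
        "versions": {"hippoasym": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {"outdir": str(outdir), "n_scans": len(records), "limits": limits}
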