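"""End-to-end orchestration: simulate -> segment -> extract -> train -> evaluate.

``run_synthetic_experiment`` executes the whole analysis in memory and is the
workhorse for tests and reproduction scripts; ``run_pipeline`` wraps it with
file outputs (masks, feature CSVs, a JSON model bundle, score CSVs, metric
tables and a JSON-lines run log) so that a human-edited vessel mask can be
swapped in between stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import evaluation, modeling, radiomics_features as rf, vessel_segmentation as vs
from .config import RunConfig
from .errors import PipelineError
from .imaging_io import write_mask
from .synthetic_data import PhantomSpec, derive_seed, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["process_case", "run_synthetic_experiment", "run_pipeline", "PIPELINE_OUTPUTS"]

# the declared stage outputs of a pipeline run directory
PIPELINE_OUTPUTS = (
    "cohort.csv",
    "vessel_masks",
    "features_tumor.csv",
    "features_vessel.csv",
    "model.json",
    "results",
)


def _vessel_params(cfg: RunConfig) -> tuple[vs.VesselnessParams, vs.VesselCleanConfig]:
    p = vs.VesselnessParams(scales=cfg.vesselness.scales, beta=cfg.vesselness.beta, c=cfg.vesselness.c)
    clean = vs.VesselCleanConfig(
        threshold=cfg.vesselness.threshold,
        min_size=cfg.vesselness.min_size,
        closing_radius=cfg.vesselness.closing_radius,
        max_hole_size=cfg.vesselness.max_hole_size,
        match_radius=cfg.vesselness.match_radius,
    )
    return p, clean


def process_case(phantom, cfg: RunConfig):
    """Segment vessels and extract tumor + vessel features for one case."""
    case_id = phantom.case_id
    params, clean = _vessel_params(cfg)
    rcfg = rf.RadiomicsConfig(
        bin_width=cfg.radiomics.bin_width,
        gldm_alpha=cfg.radiomics.gldm_alpha,
        gldm_delta=cfg.radiomics.gldm_delta,
        dependence_base=cfg.radiomics.dependence_base,
        wavelet=cfg.radiomics.wavelet,
    )
    try:
        breast = vs.segment_breast(phantom.image)
        lateral = vs.lateral_breast_mask(breast, phantom.tumor_mask_gt)
        vmap = vs.hessian_vesselness(phantom.image, params)
        # the index tumor is already delineated; its interior is not
        # vasculature, so only the rim stays contestable (automated analogue
        # of the manual erase-incorrect-voxels editing step)
        core = ndimage.binary_erosion(phantom.tumor_mask_gt.pixels, iterations=2)
        search = vs.BinaryMask(
            lateral.pixels & ~core, role=lateral.role, case_id=case_id
        ) if core.any() else lateral
        vessel = vs.binarize_and_clean(vmap, search, clean)
    except Exception as exc:
        raise PipelineError("segment", case_id, str(exc)) from exc
    if vessel.is_empty:
        raise PipelineError("segment", case_id, "no peritumoral vessel detected")
    try:
        tumor, vessel = vs.remove_tumor_overlap(phantom.tumor_mask_gt, vessel)
        detection = vs.detection_metrics(vessel, phantom.vessel_mask_gt, clean.match_radius)
    except Exception as exc:
        raise PipelineError("evaluate-seg", case_id, str(exc)) from exc
    try:
        tumor_fv = rf.extract_feature_vector(phantom.image, tumor, "tumor", rcfg)
        vessel_fv = rf.extract_feature_vector(phantom.image, vessel, "vessel", rcfg)
    except Exception as exc:
        raise PipelineError("extract", case_id, str(exc)) from exc
    return {
        "case_id": case_id,
        "label": phantom.label,
        "vessel_mask": vessel,
        "tumor_mask": tumor,
        "detection": detection,
        "tumor_features": tumor_fv,
        "vessel_features": vessel_fv,
    }


def _features_frame(results, key) -> pd.DataFrame:
    rows = {r["case_id"]: r[key].as_dict() for r in results}
    return pd.DataFrame.from_dict(rows, orient="index")


def _train_source(train_X, train_y, val_X, val_y, cfg: RunConfig, source: str):
    scaler = modeling.fit_minmax(train_X)
    train_scaled = modeling.apply_minmax(scaler, train_X)
    val_scaled = modeling.apply_minmax(scaler, val_X)
    selection = modeling.select_features_lasso_rfe(
        train_scaled, train_y, n_target=cfg.modeling.n_target,
        seed=derive_seed(cfg.seed, "rfe", source),
    )
    cols = list(selection.selected)
    knn = modeling.fit_knn(train_scaled[cols], train_y, k=cfg.modeling.k)
    scores_train = modeling.predict_scores(knn, train_scaled[cols], train_y, source=source)
    scores_val = modeling.predict_scores(knn, val_scaled[cols], val_y, source=source)
    return scaler, selection, knn, scores_train, scores_val


def run_synthetic_experiment(cfg: RunConfig | None = None, collect_masks: bool = False) -> dict:
    """Simulate two cohorts and run the full analysis; returns everything
    needed for reporting (score sets, AUC tables, detection summaries)."""
    cfg = cfg or RunConfig()
    sim = cfg.simulate
    base_spec = PhantomSpec(
        image_size=tuple(sim.image_size),
        vessel_count=sim.vessel_count,
        vessel_width_range=tuple(sim.vessel_width_range),
        tumor_radius_range=tuple(sim.tumor_radius_range),
        background_noise_sd=sim.background_noise_sd,
        class_effect=sim.class_effect,
        seed=derive_seed(cfg.seed, "phantoms"),
    )
    train_ph, train_table = generate_cohort(sim.n_train, sim.prevalence, base_spec, cohort="train")
    val_ph, val_table = generate_cohort(sim.n_validation, sim.prevalence, base_spec, cohort="validation")

    train_res = [process_case(p, cfg) for p in train_ph]
    val_res = [process_case(p, cfg) for p in val_ph]

    train_y = np.array([r["label"] for r in train_res])
    val_y = np.array([r["label"] for r in val_res])

    out = {
        "cohort": pd.concat([train_table.table, val_table.table], ignore_index=True),
        "detection": pd.DataFrame(
            [
                {
                    "case_id": r["case_id"],
                    "cohort": cohort,
                    "correct_rate": r["detection"].correct_rate,
                    "incorrect_rate": r["detection"].incorrect_rate,
                    "missed_rate": r["detection"].missed_rate,
                }
                for cohort, res in (("train", train_res), ("validation", val_res))
                for r in res
            ]
        ),
        "models": {},
        "scores": {},
    }

    features = {
        "tumor": (_features_frame(train_res, "tumor_features"), _features_frame(val_res, "tumor_features")),
        "vessel": (_features_frame(train_res, "vessel_features"), _features_frame(val_res, "vessel_features")),
    }
    out["features"] = features
    for source, (ftr, fva) in features.items():
        scaler, selection, knn, s_tr, s_va = _train_source(ftr, train_y, fva, val_y, cfg, source)
        out["models"][source] = {"scaler": scaler, "selection": selection, "knn": knn}
        out["scores"][source] = {"train": s_tr, "validation": s_va}

    grid, best = evaluation.fusion_weight_grid(
        {
            "train": (out["scores"]["tumor"]["train"], out["scores"]["vessel"]["train"]),
            "validation": (out["scores"]["tumor"]["validation"], out["scores"]["vessel"]["validation"]),
        }
    )
    out["fusion_grid"] = grid
    out["best_fusion"] = best
    out["auc"] = {
        source: {
            cohort: evaluation.roc_auc(ss).auc for cohort, ss in by_cohort.items()
        }
        for source, by_cohort in out["scores"].items()
    }
    # fused validation AUC at the grid's best rule (argmax over training cohort)
    out["auc"]["fused"] = {
        cohort: float(grid.loc[best, (cohort, "auc")]) for cohort in ("train", "validation")
    }
    if collect_masks:
        out["masks"] = {r["case_id"]: r["vessel_mask"] for res in (train_res, val_res) for r in res}
    out["train_case_ids"] = [r["case_id"] for r in train_res]
    out["validation_case_ids"] = [r["case_id"] for r in val_res]
    return out


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Run the synthetic end-to-end pipeline and write the declared outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "vessel_masks").mkdir(exist_ok=True)
    results_dir = out_dir / "results"
    results_dir.mkdir(exist_ok=True)

    res = run_synthetic_experiment(cfg, collect_masks=True)

    res["cohort"].to_csv(out_dir / "cohort.csv", index=False)
    for case_id, mask in res["masks"].items():
        write_mask(mask, out_dir / "vessel_masks" / f"{case_id}_vessel.png")
    pd.concat([res["features"]["tumor"][0], res["features"]["tumor"][1]]).to_csv(out_dir / "features_tumor.csv")
    pd.concat([res["features"]["vessel"][0], res["features"]["vessel"][1]]).to_csv(out_dir / "features_vessel.csv")

    bundles = {
        source: json.loads(
            modeling.model_bundle_to_json(m["scaler"], m["selection"], m["knn"])
        )
        for source, m in res["models"].items()
    }
    (out_dir / "model.json").write_text(json.dumps(bundles))

    score_rows = []
    for source, by_cohort in res["scores"].items():
        for cohort, ss in by_cohort.items():
            for cid, s, lab in zip(ss.case_ids, ss.scores, ss.labels):
                score_rows.append(
                    {"case_id": cid, "cohort": cohort, "source": source, "score": s, "label": lab}
                )
    pd.DataFrame(score_rows).to_csv(results_dir / "scores.csv", index=False)

    det = res["detection"]
    det_summary = det.groupby("cohort")[["correct_rate", "incorrect_rate", "missed_rate"]].agg(
        ["min", "max", "median", "mean", "std"]
    )
    det_summary.to_csv(results_dir / "detection_summary.csv")
    res["fusion_grid"].to_csv(results_dir / "fusion_grid.csv")

    cfg_json = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    log_path = results_dir / "run_log.jsonl"
    with log_path.open("w") as fh:
        fh.write(json.dumps({"event": "config", "seed": cfg.seed,
                             "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                             "config": json.loads(cfg_json)}) + "\n")
        fh.write(json.dumps({"event": "fit_inputs", "case_ids": res["train_case_ids"]}) + "\n")
        fh.write(json.dumps({"event": "validation_cases", "case_ids": res["validation_case_ids"]}) + "\n")
        for _, row in det.iterrows():
            fh.write(json.dumps({"event": "detection", **row.to_dict()}) + "\n")
        fh.write(json.dumps({"event": "auc", "auc": res["auc"], "best_fusion": res["best_fusion"]}) + "\n")
    return out_dir
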