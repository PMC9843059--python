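"""End-to-end orchestration of the analysis stages from one validated config.

Stage order: simulate -> features -> fit -> predict -> evaluate -> gsea.
A single global seed deterministically derives one sub-seed per stage
(CRC32 of the stage name), so toggling a stage never perturbs the
randomness of the others. Every run writes a manifest (config hash, seed,
stage seeds, package version, produced artifacts) — also on failure, with
the failing stage recorded.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .features import FEATURE_NAMES, patient_features, slide_features
from .genomics import filter_genes, preranked_gsea, rank_genes, shuffle_control
from .io import read_cell_map, read_clinical, read_expression, read_gmt, write_cell_map, write_clinical, write_expression, write_gmt
from .simulate import (
    CellMapSimParams,
    CohortSimParams,
    ExpressionSimParams,
    per10_log_hr,
    simulate_cell_map,
    simulate_cohort,
    simulate_expression,
)
from .survival import BenefitCoxResults, fit_penalized_cox, interaction_cox, km_logrank, median_split

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "features", "fit", "predict", "evaluate", "gsea")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage sub-seed: stable hash of the stage name mixed with the seed."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _config_hash(cfg: PipelineConfig) -> str:
    canon = yaml.safe_dump(
        json.loads(json.dumps(cfg.raw, default=str)), sort_keys=True
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _compute_patient_features(cells_dir: Path, cfg: PipelineConfig, seed: int) -> pd.DataFrame:
    rows = {}
    by_patient: dict[str, list] = {}
    for i, path in enumerate(sorted(cells_dir.glob("*.csv"))):
        cm = read_cell_map(path)
        fv = slide_features(
            cm,
            seed=seed + i,
            tile_size_px=cfg.features["tile_size_px"],
            min_tumor_cells=cfg.features["min_tumor_cells"],
            patch_side_px=cfg.features["patch_side_px"],
            max_patches=cfg.features["max_patches"],
        )
        by_patient.setdefault(cm.patient_id, []).append(fv)
    for pid, vecs in by_patient.items():
        try:
            pv = patient_features(vecs)
        except ValueError:
            logger.warning("patient %s excluded: no slide with a tumor region", pid)
            continue
        rows[pid] = pv.to_frame_row()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; returns the manifest."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in STAGE_ORDER if cfg.stages.get(s)},
        "stages_run": [],
        "artifacts": [],
        "status": "running",
    }
    paths = dict(cfg.paths)

    def emit(path: Path) -> None:
        manifest["artifacts"].append(str(path))

    try:
        if cfg.stages.get("simulate"):
            _stage_simulate(cfg, paths, out, manifest, emit)
        if cfg.stages.get("features"):
            cells_dir = Path(paths["cells_dir"])
            if not cells_dir.exists():
                raise FileNotFoundError(f"features stage: cells_dir {cells_dir} missing")
            feats = _compute_patient_features(cells_dir, cfg, stage_seed(cfg.seed, "features"))
            feats.to_csv(out / "features.csv", lineterminator="\n")
            emit(out / "features.csv")
            manifest["stages_run"].append("features")
        if cfg.stages.get("fit"):
            feats = pd.read_csv(out / "features.csv", index_col="patient_id")
            cohort = read_clinical(paths["clinical"])
            res = fit_penalized_cox(
                feats,
                cohort,
                l1_ratio=cfg.fit["l1_ratio"],
                cv_folds=cfg.fit["cv_folds"],
                seed=stage_seed(cfg.seed, "fit"),
                lambda_rule=cfg.fit["lambda_rule"],
                treated_only=cfg.fit["treated_only"],
            )
            res.save(out / "model.txt")
            res.summary().to_csv(out / "model_summary.csv", lineterminator="\n")
            emit(out / "model.txt")
            emit(out / "model_summary.csv")
            manifest["stages_run"].append("fit")
        if cfg.stages.get("predict"):
            model_path = paths.get("model") or out / "model.txt"
            res = BenefitCoxResults.load(model_path)
            feats = pd.read_csv(out / "features.csv", index_col="patient_id")
            scores = res.predict_risk(feats)
            assign = median_split(scores, threshold=cfg.split["threshold"])
            assign.to_csv(out / "assignments.csv", index_label="patient_id", lineterminator="\n")
            emit(out / "assignments.csv")
            manifest["stages_run"].append("predict")
        if cfg.stages.get("evaluate"):
            assign = pd.read_csv(out / "assignments.csv", index_col="patient_id")
            cohort = read_clinical(paths["clinical"]).set_index("patient_id")
            df = cohort.join(assign, how="inner").reset_index()
            treated = df[df["tki_treated"] == 1]
            comp = km_logrank(treated, "group")
            comp.km_table.to_csv(out / "km_table.csv", index=False, lineterminator="\n")
            inter = interaction_cox(df, group_col="group", adjust=tuple(cfg.evaluate["adjust"]))
            evaluation = {
                "logrank_chi_square": comp.chi_square,
                "logrank_p": comp.p_value,
                "group_sizes": comp.group_sizes,
                "interaction_hr": inter.hr,
                "interaction_ci": [inter.ci_low, inter.ci_high],
                "interaction_p": inter.p_value,
                "n": inter.n,
                "n_events": inter.n_events,
            }
            (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
            emit(out / "km_table.csv")
            emit(out / "evaluation.json")
            manifest["stages_run"].append("evaluate")
        if cfg.stages.get("gsea"):
            expr = read_expression(paths["expression"])
            sets = read_gmt(paths["gene_sets"])
            feats = pd.read_csv(out / "features.csv", index_col="patient_id")
            fname = cfg.gsea["feature_name"]
            fvals = feats[fname]
            expr = filter_genes(expr, cfg.gsea["max_zero_fraction"])
            ranking = rank_genes(expr, fvals, feature_name=fname)
            ranking.table.to_csv(out / "gene_ranking.csv", index_label="gene", lineterminator="\n")
            gsea_kwargs = dict(
                n_permutations=cfg.gsea["n_permutations"],
                weight_exponent=cfg.gsea["weight_exponent"],
                min_size=cfg.gsea["min_size"],
                max_size=cfg.gsea["max_size"],
            )
            res = preranked_gsea(ranking, sets, seed=stage_seed(cfg.seed, "gsea"), **gsea_kwargs)
            res.to_csv(out / "enrichment.csv", index_label="set", lineterminator="\n")
            emit(out / "gene_ranking.csv")
            emit(out / "enrichment.csv")
            if cfg.gsea["shuffle_control"]:
                ctrl = shuffle_control(
                    expr, fvals, sets, seed=stage_seed(cfg.seed, "gsea") + 1,
                    feature_name=fname, **gsea_kwargs,
                )
                ctrl.to_csv(out / "enrichment_shuffled.csv", index_label="set", lineterminator="\n")
                emit(out / "enrichment_shuffled.csv")
            manifest["stages_run"].append("gsea")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(cfg, paths, out: Path, manifest: dict, emit) -> None:
    """Generate a full synthetic study: cell maps, clinical table, expression."""
    seed = stage_seed(cfg.seed, "simulate")
    sim = cfg.simulate
    cells_dir = out / "cells"
    cells_dir.mkdir(parents=True, exist_ok=True)
    theta = sim["theta"]
    rng = np.random.default_rng(seed)
    if isinstance(theta, (list, tuple)):
        lo, hi = (theta[0], theta[-1])
        thetas = rng.uniform(lo, hi, size=sim["n_patients"])
    else:
        thetas = np.full(sim["n_patients"], float(theta))
    for i in range(sim["n_patients"]):
        cm = simulate_cell_map(
            CellMapSimParams(theta=float(thetas[i])),
            seed=seed + i,
            slide_id=f"S{i:04d}",
            patient_id=f"P{i:04d}",
        )
        write_cell_map(cm, cells_dir / f"{cm.slide_id}.csv")
    emit(cells_dir)
    paths["cells_dir"] = cells_dir

    # cohort from the slides' measured features (planted effects optional)
    feats = _compute_patient_features(cells_dir, cfg, seed + 90001)
    beta = (
        {"interaction_tumor_tumor": per10_log_hr(0.73), "interaction_tumor_stroma": per10_log_hr(1.53)}
        if sim["plant_effects"]
        else {}
    )
    cohort = simulate_cohort(
        feats[list(FEATURE_NAMES)],
        CohortSimParams(beta=beta, treat_fraction=sim["treat_fraction"]),
        seed=seed + 90002,
    )
    clinical_path = out / "clinical.csv"
    write_clinical(cohort, clinical_path)
    emit(clinical_path)
    paths["clinical"] = clinical_path

    if sim["expression"]:
        fvals = feats["interaction_tumor_stroma"]
        expr, sets = simulate_expression(fvals, ExpressionSimParams(), seed=seed + 90003)
        write_expression(expr, out / "expression.tsv")
        write_gmt(sets, out / "gene_sets.gmt")
        emit(out / "expression.tsv")
        emit(out / "gene_sets.gmt")
        paths["expression"] = out / "expression.tsv"
        paths["gene_sets"] = out / "gene_sets.gmt"
    manifest["stages_run"].append("simulate")
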