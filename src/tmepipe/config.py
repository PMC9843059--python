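"""Pipeline configuration: YAML parsing, defaults, and strict validation.

Defaults mirror the pipeline's standard operating point: 500 px tumor tiles
with a 10-cell threshold, 1024 px patches capped at 100 per slide, a 0.20
gene zero-fraction filter, elastic-net mixing weight 0.5 with 5-fold
cross-validation. Unknown keys are rejected so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "out",
    "stages": {
        "simulate": False,
        "features": True,
        "fit": True,
        "predict": True,
        "evaluate": True,
        "gsea": False,
    },
    "paths": {
        "cells_dir": None,
        "clinical": None,
        "expression": None,
        "gene_sets": None,
        "model": None,
    },
    "features": {
        "tile_size_px": 500,
        "min_tumor_cells": 10,
        "patch_side_px": 1024,
        "max_patches": 100,
    },
    "fit": {
        "l1_ratio": 0.5,
        "cv_folds": 5,
        "lambda_rule": "min",
        "treated_only": True,
    },
    "split": {"threshold": None},
    "evaluate": {"adjust": ["age", "sex", "smoking_status", "surgery"]},
    "gsea": {
        "feature_name": "interaction_tumor_stroma",
        "n_permutations": 1000,
        "weight_exponent": 1.0,
        "min_size": 5,
        "max_size": 500,
        "max_zero_fraction": 0.20,
        "shuffle_control": False,
    },
    "simulate": {
        "n_patients": 40,
        "theta": [0.0, 1.0],  # scalar, or [lo, hi] for per-patient Uniform draw
        "treat_fraction": 0.5,
        "plant_effects": True,
        "expression": True,
    },
}

_POSITIVE_INT_KEYS = {
    ("features", "tile_size_px"),
    ("features", "min_tumor_cells"),
    ("features", "patch_side_px"),
    ("features", "max_patches"),
    ("fit", "cv_folds"),
    ("gsea", "n_permutations"),
    ("gsea", "min_size"),
    ("gsea", "max_size"),
    ("simulate", "n_patients"),
}


class ConfigError(ValueError):
    """The configuration file is malformed or out of range."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline settings; see module docstring for the schema."""

    seed: int
    out_dir: Path
    stages: dict
    paths: dict
    features: dict
    fit: dict
    split: dict
    evaluate: dict
    gsea: dict
    simulate: dict
    raw: dict = field(repr=False, default_factory=dict)


def _merge_strict(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {prefix + key!r}")
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            raise ConfigError(f"section {prefix + key!r} must be a mapping")
        if isinstance(defaults[key], dict):
            out[key] = _merge_strict(defaults[key], value, prefix=f"{prefix}{key}.")
        else:
            out[key] = value
    return out


def validate_config(source) -> PipelineConfig:
    """Parse and validate a YAML config file (or a pre-parsed mapping)."""
    if isinstance(source, dict):
        user = source
    else:
        text = Path(source).read_text(encoding="utf-8")
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{source}: top level must be a mapping")
    merged = _merge_strict(_DEFAULTS, user)

    for section, key in _POSITIVE_INT_KEYS:
        v = merged[section][key]
        if not isinstance(v, int) or v <= 0:
            raise ConfigError(f"{section}.{key} must be a positive integer, got {v!r}")
    if not 0.0 <= merged["fit"]["l1_ratio"] <= 1.0:
        raise ConfigError("fit.l1_ratio must lie in [0, 1]")
    if merged["fit"]["lambda_rule"] not in ("min", "1se"):
        raise ConfigError("fit.lambda_rule must be 'min' or '1se'")
    if not 0.0 <= merged["gsea"]["max_zero_fraction"] <= 1.0:
        raise ConfigError("gsea.max_zero_fraction must lie in [0, 1]")
    theta = merged["simulate"]["theta"]
    theta_vals = theta if isinstance(theta, (list, tuple)) else [theta]
    if (
        not theta_vals
        or len(theta_vals) > 2
        or any(not isinstance(v, (int, float)) or not 0.0 <= v <= 1.0 for v in theta_vals)
    ):
        raise ConfigError("simulate.theta must be a value in [0, 1] or a [lo, hi] pair")

    stages = merged["stages"]
    paths = merged["paths"]
    if not stages.get("simulate"):
        # inputs must already exist for the stages that consume them
        requirements = {
            "features": ["cells_dir"],
            "fit": ["clinical"],
            "evaluate": ["clinical"],
            "gsea": ["expression", "gene_sets"],
        }
        for stage, needed in requirements.items():
            if stages.get(stage):
                for key in needed:
                    if not paths.get(key):
                        raise ConfigError(
                            f"stage {stage!r} enabled but paths.{key} is not set"
                        )
                    if not Path(paths[key]).exists():
                        raise ConfigError(
                            f"paths.{key} = {paths[key]!r} does not exist"
                        )
    return PipelineConfig(
        seed=int(merged["seed"]),
        out_dir=Path(merged["out_dir"]),
        stages=stages,
        paths=paths,
        features=merged["features"],
        fit=merged["fit"],
        split=merged["split"],
        evaluate=merged["evaluate"],
        gsea=merged["gsea"],
        simulate=merged["simulate"],
        raw=merged,
    )
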