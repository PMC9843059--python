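"""Simulation studies validating each stage of the pipeline.

Each function runs a self-contained study on synthetic data and returns the
measured quantity (an agreement fraction, a coverage rate, a rejection rate,
...). They back both the test suite and the reproduction script, so every
reported number is recomputed from scratch by the package itself.

The module also carries an independent brute-force Delaunay reference
(:func:`brute_force_delaunay_edges`, the O(n^4) empty-circumcircle
definition) used to cross-check the geometry path.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .features import (
    INTERACTION_FEATURES,
    Patch,
    build_delaunay,
    detect_tumor_tiles,
    patch_interactions,
    slide_features,
)
from .genomics import filter_genes, preranked_gsea, rank_genes, shuffle_control
from .io import CELL_TYPES, CellMap
from .simulate import (
    CellMapSimParams,
    CohortSimParams,
    ExpressionSimParams,
    per10_log_hr,
    simulate_cell_map,
    simulate_cohort,
    simulate_expression,
    simulate_features,
    simulate_interaction_cohort,
)
from .survival import cox_hr, fit_penalized_cox, interaction_cox

TT = "interaction_tumor_tumor"
TS = "interaction_tumor_stroma"


# ---------------------------------------------------------------------------
# geometry


def random_patch(rng: np.random.Generator, n_cells: int, side: float = 1024.0) -> Patch:
    """Random mixed-type patch; tumor-rich so interactions are usually defined."""
    pts = rng.uniform(0, side, size=(n_cells, 2))
    types = rng.choice(CELL_TYPES, size=n_cells, p=[0.4, 0.2, 0.15, 0.1, 0.08, 0.07])
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "x": pts[:, 0],
            "y": pts[:, 1],
            "cell_type": types,
        }
    )
    return Patch(x0=0, y0=0, side_x=int(side), side_y=int(side), cells=cells)


def brute_force_delaunay_edges(points: np.ndarray, chunk: int = 20000) -> set[tuple[int, int]]:
    """Delaunay edge set by the empty-circumcircle definition over all triples.

    Independent of scipy's Qhull path: a triangle belongs to the
    triangulation iff no other point lies strictly inside its circumcircle.
    Assumes points in general position (no 4 cocircular, no 3 collinear).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    triples = np.array(list(combinations(range(n), 3)))
    for start in range(0, len(triples), chunk):
        t = triples[start : start + chunk]
        a, b, c = pts[t[:, 0]], pts[t[:, 1]], pts[t[:, 2]]
        d = 2.0 * (
            a[:, 0] * (b[:, 1] - c[:, 1])
            + b[:, 0] * (c[:, 1] - a[:, 1])
            + c[:, 0] * (a[:, 1] - b[:, 1])
        )
        ok = np.abs(d) > 1e-12  # skip collinear triples
        if not ok.any():
            continue
        t, a, b, c, d = t[ok], a[ok], b[ok], c[ok], d[ok]
        a2 = (a**2).sum(axis=1)
        b2 = (b**2).sum(axis=1)
        c2 = (c**2).sum(axis=1)
        ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d
        uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d
        centers = np.column_stack([ux, uy])
        r2 = ((a - centers) ** 2).sum(axis=1)
        d2 = ((centers[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)  # (T, n)
        d2[np.arange(len(t))[:, None], t] = np.inf  # the triangle's own vertices
        empty = d2.min(axis=1) > r2 * (1.0 - 1e-9)
        for i, j, k in t[empty]:
            edges.add((min(i, j), max(i, j)))
            edges.add((min(j, k), max(j, k)))
            edges.add((min(i, k), max(i, k)))
    return edges


def brute_force_interactions(points: np.ndarray, types: np.ndarray) -> pd.Series:
    """Interaction fractions by direct enumeration over the brute-force edge set."""
    edges = brute_force_delaunay_edges(points)
    out = pd.Series(np.nan, index=list(INTERACTION_FEATURES), dtype=float)
    incident = [(i, j) for i, j in edges if types[i] == "tumor" or types[j] == "tumor"]
    if not incident:
        return out
    partners = [types[j] if types[i] == "tumor" else types[i] for i, j in incident]
    for k in CELL_TYPES:
        out[f"interaction_tumor_{k}"] = partners.count(k) / len(incident)
    return out


def conservation_study(n_patches: int = 100, seed: int = 0) -> dict:
    """Sum-to-one, range and similarity-invariance checks on random patches."""
    rng = np.random.default_rng(seed)
    max_sum_err = 0.0
    lo, hi = np.inf, -np.inf
    max_invariance_dev = 0.0
    n_defined = 0
    for _ in range(n_patches):
        patch = random_patch(rng, int(rng.integers(20, 200)))
        inter = patch_interactions(build_delaunay(patch))
        if inter.isna().all():
            continue
        n_defined += 1
        max_sum_err = max(max_sum_err, abs(inter.sum() - 1.0))
        lo, hi = min(lo, inter.min()), max(hi, inter.max())
        # similarity transform: translate, rotate, uniform scale
        theta = rng.uniform(0, 2 * np.pi)
        s = rng.uniform(0.5, 3.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pts = patch.cells[["x", "y"]].to_numpy() @ rot.T * s + rng.uniform(-500, 500, 2)
        moved = Patch(
            x0=0,
            y0=0,
            side_x=patch.side_x,
            side_y=patch.side_y,
            cells=patch.cells.assign(x=pts[:, 0], y=pts[:, 1]),
        )
        inter2 = patch_interactions(build_delaunay(moved))
        max_invariance_dev = max(max_invariance_dev, float((inter - inter2).abs().max()))
    return {
        "n_patches": n_patches,
        "n_defined": n_defined,
        "max_sum_error": max_sum_err,
        "min_fraction": float(lo),
        "max_fraction": float(hi),
        "max_similarity_deviation": max_invariance_dev,
    }


def delaunay_oracle_study(n_patches: int = 50, max_cells: int = 100, seed: int = 0) -> dict:
    """Edge-set and interaction agreement with the brute-force oracle."""
    rng = np.random.default_rng(seed)
    edge_agree = 0
    inter_agree = 0
    for _ in range(n_patches):
        patch = random_patch(rng, int(rng.integers(10, max_cells + 1)))
        graph = build_delaunay(patch)
        fast_edges = {tuple(e) for e in graph.edges}
        pts = patch.cells[["x", "y"]].to_numpy()
        types = patch.cells["cell_type"].to_numpy()
        oracle_edges = brute_force_delaunay_edges(pts)
        if fast_edges == oracle_edges:
            edge_agree += 1
        fast_inter = patch_interactions(graph)
        oracle_inter = brute_force_interactions(pts, types)
        both_nan = fast_inter.isna().all() and oracle_inter.isna().all()
        if both_nan or np.allclose(
            fast_inter.to_numpy(float), oracle_inter.to_numpy(float), atol=1e-12, equal_nan=True
        ):
            inter_agree += 1
    return {
        "n_patches": n_patches,
        "edge_agreement": edge_agree / n_patches,
        "interaction_agreement": inter_agree / n_patches,
    }


def tile_threshold_sweep(
    tile_size: int = 500, min_tumor_cells: int = 10, max_count: int = 20
) -> dict:
    """Selected-vs-count profile of tumor-tile detection over counts 0..max_count."""
    selected_at = []
    rng = np.random.default_rng(12345)
    for count in range(max_count + 1):
        pts = rng.uniform(0, tile_size, size=(count, 2))
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(count)],
                "x": pts[:, 0],
                "y": pts[:, 1],
                "cell_type": "tumor",
            }
        )
        cm = CellMap(
            slide_id="S", patient_id="P", width_px=tile_size, height_px=tile_size, cells=cells
        )
        roi = detect_tumor_tiles(cm, tile_size, min_tumor_cells)
        selected_at.append(len(roi.selected) == 1)
    flips = [c for c in range(1, max_count + 1) if selected_at[c] != selected_at[c - 1]]
    return {
        "profile": selected_at,
        "n_flips": len(flips),
        "flip_count": flips[0] if len(flips) == 1 else None,
    }


def mixing_monotonicity_study(
    thetas: tuple = (0.0, 0.25, 0.5, 0.75, 1.0), n_seeds: int = 20, seed: int = 0
) -> dict:
    """Mean slide-level tumor-stroma interaction across the stromal mixing grid."""
    means = []
    for level, theta in enumerate(thetas):
        vals = []
        for r in range(n_seeds):
            s = seed + 1000 * level + r
            cm = simulate_cell_map(CellMapSimParams(theta=theta), seed=s)
            fv = slide_features(cm, seed=s)
            vals.append(fv.values[TS])
        means.append(float(np.nanmean(vals)))
    diffs = np.diff(means)
    return {
        "thetas": list(thetas),
        "mean_tumor_stroma_interaction": means,
        "strictly_increasing": bool((diffs > 0).all()),
        "theta0_mean": means[0],
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# survival model


def planted_betas() -> dict:
    """Per-unit log-hazards for the planted per-10% HRs 0.73 (t-t) and 1.53 (t-s)."""
    return {TT: per10_log_hr(0.73), TS: per10_log_hr(1.53)}


def selection_recovery_study(
    n_reps: int = 50, n_patients: int = 400, seed: int = 0, lambda_rule: str = "1se"
) -> dict:
    """How often the elastic net selects exactly the two planted features with
    the planted signs (tumor-tumor protective, tumor-stroma harmful)."""
    params = CohortSimParams(beta=planted_betas(), treat_fraction=1.0)
    hits = 0
    exact = 0
    for r in range(n_reps):
        feats = simulate_features(n_patients, seed=seed + 7919 * r)
        cohort = simulate_cohort(feats, params, seed=seed + 7919 * r + 1)
        res = fit_penalized_cox(
            feats, cohort, seed=seed + r, lambda_rule=lambda_rule, treated_only=True
        )
        sel = set(res.selected_features)
        ok = {TT, TS} <= sel and res.coefficients[TT] < 0 and res.coefficients[TS] > 0
        hits += int(ok)
        exact += int(ok and sel == {TT, TS})
    return {
        "n_reps": n_reps,
        "recovery_rate": hits / n_reps,
        "exact_set_rate": exact / n_reps,
    }


def hr_coverage_study(n_reps_per_feature: int = 100, n_patients: int = 1000, seed: int = 0) -> dict:
    """CI coverage of univariate Cox for the planted per-10% HRs.

    Each replicate plants a single nonzero coefficient (so the univariate
    model is correctly specified) and checks whether the Wald 95% CI on the
    per-10% scale covers the planted value.
    """
    truths = {TT: 0.73, TS: 1.53}
    cover = {TT: 0, TS: 0}
    for feat, hr_true in truths.items():
        params = CohortSimParams(beta={feat: per10_log_hr(hr_true)}, treat_fraction=1.0)
        for r in range(n_reps_per_feature):
            s = seed + 104729 * r + (0 if feat == TT else 1)
            feats = simulate_features(n_patients, seed=s)
            cohort = simulate_cohort(feats, params, seed=s + 13)
            df = cohort.set_index("patient_id").join(feats[[feat]])
            res = cox_hr(df, feat).per10()
            if res.converged and res.ci_low <= hr_true <= res.ci_high:
                cover[feat] += 1
    n_total = 2 * n_reps_per_feature
    return {
        "n_reps": n_total,
        "coverage_tumor_tumor": cover[TT] / n_reps_per_feature,
        "coverage_tumor_stroma": cover[TS] / n_reps_per_feature,
        "coverage_overall": (cover[TT] + cover[TS]) / n_total,
    }


def interaction_calibration_study(
    n_null: int = 1000, n_power: int = 100, n_patients: int = 600, seed: int = 0
) -> dict:
    """Type-I error under no effect modification and power under a
    benefit-group-restricted treatment effect (treated benefit hazard x 0.2)."""
    rej_null = 0
    for r in range(n_null):
        df = simulate_interaction_cohort(n_patients, 1.0, 1.0, seed=seed + r)
        res = interaction_cox(df)
        rej_null += int(res.p_value < 0.05)
    rej_alt = 0
    for r in range(n_power):
        df = simulate_interaction_cohort(n_patients, 0.2, 1.0, seed=seed + 50021 + r)
        res = interaction_cox(df)
        rej_alt += int(res.p_value < 0.05)
    return {
        "n_null": n_null,
        "n_power": n_power,
        "type_i_error": rej_null / n_null,
        "power": rej_alt / n_power,
    }


# ---------------------------------------------------------------------------
# image-genomics


def gsea_recovery_study(
    n_reps: int = 20, n_patients: int = 60, n_permutations: int = 10000, seed: int = 0
) -> dict:
    """Planted-set recovery and its destruction under the patient-ID shuffle."""
    recovered = 0
    destroyed = 0
    params = ExpressionSimParams()
    for r in range(n_reps):
        s = seed + 60013 * r
        feats = simulate_features(n_patients, seed=s)
        fvals = feats[TS]
        expr, sets = simulate_expression(fvals, params, seed=s + 1)
        expr = filter_genes(expr)
        ranking = rank_genes(expr, fvals, feature_name=TS)
        res = preranked_gsea(ranking, sets, n_permutations=n_permutations, seed=s + 2)
        planted = res.loc["PLANTED"]
        top = res["p_adjusted"].idxmin() == "PLANTED"
        recovered += int(top and planted["p_adjusted"] < 0.05)
        ctrl = shuffle_control(
            expr, fvals, sets, seed=s + 3, feature_name=TS, n_permutations=n_permutations
        )
        destroyed += int(ctrl.loc["PLANTED", "p_adjusted"] >= 0.05)
    return {
        "n_reps": n_reps,
        "recovery_rate": recovered / n_reps,
        "shuffle_nonsignificant_rate": destroyed / n_reps,
    }
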