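"""Tumor-microenvironment image features from nuclei centroid maps.

One slide is summarized by 12 features plus the tumor/stroma ratio (TSR):

* six cell densities — the mean number of nuclei of each type per sampled
  1024 x 1024 px patch inside the tumor region, and
* six tumor-X interaction fractions — on the Delaunay triangulation of each
  patch's nuclei, the fraction of edges incident to a tumor cell whose other
  endpoint is of type X (tumor-tumor edges counted once).

The tumor region of interest is the set of 500 x 500 px grid tiles containing
at least 10 tumor nuclei; up to 100 patches are sampled, each centered on a
distinct selected tile and clamped into the slide. Interaction fractions of a
patch sum to 1 whenever the patch has any tumor-incident edge; patches with no
tumor-incident edge (or a degenerate triangulation) are excluded from the
interaction average but still contribute to densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .io import CELL_TYPES, CellMap

logger = logging.getLogger(__name__)

DENSITY_FEATURES = tuple(f"density_{t}" for t in CELL_TYPES)
INTERACTION_FEATURES = tuple(f"interaction_tumor_{t}" for t in CELL_TYPES)
FEATURE_NAMES: tuple[str, ...] = DENSITY_FEATURES + INTERACTION_FEATURES


@dataclass(frozen=True)
class TumorROI:
    """Tumor region of a slide as selected tiles of a regular grid."""

    tile_size_px: int
    min_tumor_cells: int
    tile_counts: pd.DataFrame = field(repr=False)  # tile_row, tile_col, n_tumor
    selected: frozenset  # of (tile_row, tile_col)
    n_tile_rows: int
    n_tile_cols: int

    def __len__(self) -> int:
        return len(self.selected)


@dataclass(frozen=True)
class Patch:
    """A square pixel window and the member cells it contains."""

    x0: int
    y0: int
    side_x: int
    side_y: int
    cells: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class NeighborGraph:
    """Delaunay edge set of one patch; degenerate graphs carry zero edges."""

    cell_types: np.ndarray  # per-vertex type labels
    edges: np.ndarray  # (n_edges, 2) vertex indices, i < j
    degenerate: bool = False

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class FeatureVector:
    """The 12 image features plus TSR at patch, slide or patient level."""

    values: pd.Series  # indexed by FEATURE_NAMES; interactions NaN when undefined
    level: str  # {"patch", "slide", "patient"}
    tsr: float = float("nan")
    n_patches_used: int = 0
    no_tumor: bool = False

    def to_frame_row(self) -> dict:
        row = dict(self.values)
        row.update(
            tsr=self.tsr,
            n_patches_used=self.n_patches_used,
            level=self.level,
            no_tumor=self.no_tumor,
        )
        return row


def detect_tumor_tiles(
    cell_map: CellMap, tile_size_px: int = 500, min_tumor_cells: int = 10
) -> TumorROI:
    """Partition the slide into a regular tile grid and select tumor tiles.

    A tile is selected iff it contains at least ``min_tumor_cells`` tumor
    nuclei. Edge tiles narrower than ``tile_size_px`` use the same absolute
    count threshold (logged, no area proration).
    """
    if tile_size_px <= 0:
        raise ValueError("tile_size_px must be > 0")
    n_rows = -(-cell_map.height_px // tile_size_px)
    n_cols = -(-cell_map.width_px // tile_size_px)
    cells = cell_map.cells
    tumor = cells[cells["cell_type"] == "tumor"]
    if len(tumor):
        rows = (tumor["y"].to_numpy() // tile_size_px).astype(int)
        cols = (tumor["x"].to_numpy() // tile_size_px).astype(int)
        counts = (
            pd.DataFrame({"tile_row": rows, "tile_col": cols})
            .value_counts()
            .rename("n_tumor")
            .reset_index()
            .sort_values(["tile_row", "tile_col"], ignore_index=True)
        )
    else:
        counts = pd.DataFrame(columns=["tile_row", "tile_col", "n_tumor"])
    selected = frozenset(
        (int(r), int(c))
        for r, c, n in counts.itertuples(index=False)
        if n >= min_tumor_cells
    )
    if (cell_map.width_px % tile_size_px or cell_map.height_px % tile_size_px) and selected:
        logger.debug(
            "slide %s: edge tiles narrower than %d px use the absolute threshold",
            cell_map.slide_id,
            tile_size_px,
        )
    return TumorROI(
        tile_size_px=tile_size_px,
        min_tumor_cells=min_tumor_cells,
        tile_counts=counts,
        selected=selected,
        n_tile_rows=int(n_rows),
        n_tile_cols=int(n_cols),
    )


def extract_patch(cell_map: CellMap, x0: int, y0: int, side_px: int) -> Patch:
    """Cells with x0 <= x < x0+side, y0 <= y < y0+side; window clamped to the slide."""
    side_x = min(side_px, cell_map.width_px)
    side_y = min(side_px, cell_map.height_px)
    x0 = int(np.clip(x0, 0, cell_map.width_px - side_x))
    y0 = int(np.clip(y0, 0, cell_map.height_px - side_y))
    c = cell_map.cells
    mask = (
        (c["x"] >= x0)
        & (c["x"] < x0 + side_x)
        & (c["y"] >= y0)
        & (c["y"] < y0 + side_y)
    )
    return Patch(x0=x0, y0=y0, side_x=side_x, side_y=side_y, cells=c[mask].reset_index(drop=True))


def sample_patches(
    roi: TumorROI,
    cell_map: CellMap,
    side_px: int = 1024,
    max_patches: int = 100,
    seed: int = 0,
) -> list[Patch]:
    """Sample up to ``max_patches`` patches centered on distinct tumor tiles.

    Tile centers are drawn uniformly without replacement; each patch is
    clamped to lie within the slide. Deterministic given ``seed``.
    """
    if not roi.selected:
        logger.warning("empty tumor ROI: no patches sampled")
        return []
    tiles = sorted(roi.selected)
    rng = np.random.default_rng(seed)
    k = min(max_patches, len(tiles))
    chosen = rng.choice(len(tiles), size=k, replace=False)
    patches = []
    half = side_px // 2
    for idx in chosen:
        r, c = tiles[idx]
        cx = c * roi.tile_size_px + roi.tile_size_px // 2
        cy = r * roi.tile_size_px + roi.tile_size_px // 2
        patches.append(extract_patch(cell_map, cx - half, cy - half, side_px))
    return patches


def build_delaunay(patch: Patch) -> NeighborGraph:
    """Delaunay triangulation edge set of the patch's cell centroids.

    Fewer than 3 cells, or an all-collinear configuration, yields a flagged
    degenerate graph with zero edges.
    """
    types = patch.cells["cell_type"].to_numpy()
    pts = patch.cells[["x", "y"]].to_numpy(float)
    if len(pts) < 3:
        return NeighborGraph(types, np.empty((0, 2), dtype=int), degenerate=True)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return NeighborGraph(types, np.empty((0, 2), dtype=int), degenerate=True)
    simplices = tri.simplices
    edges = np.concatenate(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]]
    )
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    return NeighborGraph(types, edges)


def patch_interactions(graph: NeighborGraph) -> pd.Series:
    """Tumor-X interaction fractions from a neighbor graph.

    I(tumor, k) = (# edges joining a tumor cell to a type-k cell) /
    (# edges incident to at least one tumor cell); tumor-tumor edges count
    once in both numerator and denominator. All six values are NaN when no
    tumor-incident edge exists.
    """
    out = pd.Series(np.nan, index=list(INTERACTION_FEATURES), dtype=float)
    if graph.degenerate or graph.n_edges == 0:
        return out
    ta = graph.cell_types[graph.edges[:, 0]]
    tb = graph.cell_types[graph.edges[:, 1]]
    incident = (ta == "tumor") | (tb == "tumor")
    denom = int(incident.sum())
    if denom == 0:
        return out
    # other endpoint's type; for tumor-tumor edges the partner is tumor
    partner = np.where(ta[incident] == "tumor", tb[incident], ta[incident])
    for k in CELL_TYPES:
        out[f"interaction_tumor_{k}"] = float((partner == k).sum()) / denom
    return out


def patch_densities(patch: Patch) -> pd.Series:
    """Per-patch cell counts by type (the density features before averaging)."""
    counts = patch.cells["cell_type"].value_counts().reindex(CELL_TYPES, fill_value=0)
    return pd.Series(counts.to_numpy(float), index=list(DENSITY_FEATURES))


def compute_tsr(cell_map: CellMap, roi: TumorROI) -> float:
    """Tumor/stroma cell-count ratio within the selected tumor tiles.

    NaN when the ROI is empty or contains no stroma cells.
    """
    if not roi.selected:
        return float("nan")
    c = cell_map.cells
    rows = (c["y"].to_numpy() // roi.tile_size_px).astype(int)
    cols = (c["x"].to_numpy() // roi.tile_size_px).astype(int)
    inside = np.fromiter(
        ((r, cc) in roi.selected for r, cc in zip(rows, cols)),
        dtype=bool,
        count=len(c),
    )
    types = c["cell_type"].to_numpy()[inside]
    n_tumor = int((types == "tumor").sum())
    n_stroma = int((types == "stroma").sum())
    if n_stroma == 0:
        return float("nan")
    return n_tumor / n_stroma


def patch_features(patch: Patch) -> FeatureVector:
    graph = build_delaunay(patch)
    values = pd.concat([patch_densities(patch), patch_interactions(graph)])
    return FeatureVector(values=values, level="patch", n_patches_used=1)


def slide_features(
    cell_map: CellMap,
    seed: int = 0,
    tile_size_px: int = 500,
    min_tumor_cells: int = 10,
    patch_side_px: int = 1024,
    max_patches: int = 100,
) -> FeatureVector:
    """Full per-slide pipeline: tumor ROI -> patch sample -> per-patch features -> mean.

    Densities average over all sampled patches; interactions average only over
    patches where they are defined. A slide with no tumor tiles is returned
    flagged ``no_tumor`` (such slides are excluded from patient aggregation).
    """
    roi = detect_tumor_tiles(cell_map, tile_size_px, min_tumor_cells)
    tsr = compute_tsr(cell_map, roi)
    if not roi.selected:
        logger.warning("slide %s: no tumor tiles; flagged no-tumor", cell_map.slide_id)
        values = pd.Series(np.nan, index=list(FEATURE_NAMES))
        return FeatureVector(values=values, level="slide", tsr=tsr, no_tumor=True)
    patches = sample_patches(roi, cell_map, patch_side_px, max_patches, seed)
    rows = pd.DataFrame([patch_features(p).values for p in patches])
    values = rows.mean(axis=0, skipna=True)  # interactions: mean over defined patches
    return FeatureVector(
        values=values[list(FEATURE_NAMES)],
        level="slide",
        tsr=tsr,
        n_patches_used=len(patches),
    )


def patient_features(slide_vectors: list[FeatureVector]) -> FeatureVector:
    """Unweighted mean of non-flagged slide vectors for one patient."""
    usable = [v for v in slide_vectors if not v.no_tumor]
    if not usable:
        raise ValueError("patient has no slide with a tumor region")
    values = pd.DataFrame([v.values for v in usable]).mean(axis=0)
    tsrs = [v.tsr for v in usable if np.isfinite(v.tsr)]
    return FeatureVector(
        values=values[list(FEATURE_NAMES)],
        level="patient",
        tsr=float(np.mean(tsrs)) if tsrs else float("nan"),
        n_patches_used=sum(v.n_patches_used for v in usable),
    )


def feature_table(vectors: dict[str, FeatureVector]) -> pd.DataFrame:
    """Feature vectors keyed by id -> tidy table (one row per id)."""
    rows = {k: v.to_frame_row() for k, v in vectors.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df
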