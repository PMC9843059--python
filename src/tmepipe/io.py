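"""Domain types and file I/O for cell maps, clinical tables, expression and gene sets.

All tabular files are comma-separated UTF-8 with a mandatory header row; an
empty field denotes a missing value. Cell-map files additionally carry the
slide extent and pixel resolution in a single leading ``#meta:`` comment line
so that read/write round-trips are lossless.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The six nucleus classes produced by the upstream H&E segmentation model.
CELL_TYPES: tuple[str, ...] = (
    "tumor",
    "stroma",
    "lymphocyte",
    "red_blood_cell",
    "macrophage",
    "karyorrhexis",
)

EGFR_CLASSES: tuple[str, ...] = ("sensitizing", "other")

_CELL_COLUMNS = ["slide_id", "patient_id", "cell_id", "x_px", "y_px", "cell_type"]
_CLINICAL_COLUMNS = [
    "patient_id",
    "os_months",
    "event",
    "tki_treated",
    "egfr_class",
    "age",
    "sex",
    "smoking_status",
    "surgery",
]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


@dataclass(frozen=True)
class CellMap:
    """All detected nuclei of one slide.

    ``cells`` has columns ``cell_id`` (str), ``x`` / ``y`` (float pixel
    coordinates, origin top-left, x rightward, y downward) and ``cell_type``
    (one of :data:`CELL_TYPES`). Coordinates live in the half-open extent
    ``[0, width_px) x [0, height_px)``.
    """

    slide_id: str
    patient_id: str
    width_px: int
    height_px: int
    cells: pd.DataFrame = field(repr=False)
    microns_per_pixel: float = 0.25

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError(
                f"slide extent must be positive, got {self.width_px}x{self.height_px}"
            )
        if self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel must be > 0")
        c = self.cells
        missing = {"cell_id", "x", "y", "cell_type"} - set(c.columns)
        if missing:
            raise ValidationError(f"cells frame missing columns: {sorted(missing)}")
        if len(c):
            bad = ~c["cell_type"].isin(CELL_TYPES)
            if bad.any():
                offending = c.loc[bad, "cell_type"].iloc[0]
                raise ValidationError(
                    f"unknown cell type {offending!r} (row {int(np.flatnonzero(bad)[0])})"
                )
            xy = c[["x", "y"]].to_numpy(float)
            if not np.isfinite(xy).all():
                raise ValidationError("non-finite cell coordinates")
            if (
                (xy[:, 0] < 0).any()
                or (xy[:, 1] < 0).any()
                or (xy[:, 0] >= self.width_px).any()
                or (xy[:, 1] >= self.height_px).any()
            ):
                raise ValidationError("cell coordinates outside the slide extent")
            if c["cell_id"].duplicated().any():
                dup = c.loc[c["cell_id"].duplicated(), "cell_id"].iloc[0]
                raise ValidationError(f"duplicate cell_id {dup!r} within slide")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def counts_by_type(self) -> pd.Series:
        """Cell counts per type, indexed by the full six-type vocabulary."""
        return (
            self.cells["cell_type"].value_counts().reindex(CELL_TYPES, fill_value=0)
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets; set names unique, each set a nonempty tuple of symbols."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def filtered(self, universe, min_size: int, max_size: int) -> "GeneSetCollection":
        """Restrict members to ``universe`` and drop sets outside the size window."""
        universe = set(universe)
        kept: dict[str, tuple[str, ...]] = {}
        for name, members in self.sets.items():
            inside = tuple(g for g in members if g in universe)
            if min_size <= len(inside) <= max_size:
                kept[name] = inside
        return GeneSetCollection(
            kept, {k: v for k, v in self.descriptions.items() if k in kept}
        )


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_cell_map(path) -> CellMap:
    """Read one slide's nuclei table (core dialect, see module docstring)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#meta:"):
            for kv in first[len("#meta:"):].strip().split(","):
                k, _, v = kv.partition("=")
                meta[k.strip()] = v.strip()
            body = fh.read()
        else:
            body = first + fh.read()
    if not body.strip():
        raise FormatError(f"{path}: empty file, header row is mandatory")
    df = pd.read_csv(_stdio.StringIO(body), dtype=str, keep_default_na=False)
    _require_columns(df, _CELL_COLUMNS, path)
    if len(df):
        bad = ~df["cell_type"].isin(CELL_TYPES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: unknown cell type {df['cell_type'].iloc[row]!r} at data row {row + 1}"
            )
        slide_ids = df["slide_id"].unique()
        if len(slide_ids) > 1:
            raise ValidationError(f"{path}: multiple slide_ids in one cell map: {list(slide_ids)}")
    cells = pd.DataFrame(
        {
            "cell_id": df["cell_id"].to_numpy(),
            "x": pd.to_numeric(df["x_px"], errors="raise").astype(float),
            "y": pd.to_numeric(df["y_px"], errors="raise").astype(float),
            "cell_type": df["cell_type"].to_numpy(),
        }
    )
    slide_id = df["slide_id"].iloc[0] if len(df) else meta.get("slide_id", "")
    patient_id = df["patient_id"].iloc[0] if len(df) else meta.get("patient_id", "")
    if len(cells):
        default_w = int(np.floor(cells["x"].max())) + 1
        default_h = int(np.floor(cells["y"].max())) + 1
    else:
        default_w = default_h = 1
    return CellMap(
        slide_id=slide_id,
        patient_id=patient_id,
        width_px=int(meta.get("width_px", default_w)),
        height_px=int(meta.get("height_px", default_h)),
        microns_per_pixel=float(meta.get("microns_per_pixel", 0.25)),
        cells=cells,
    )


def write_cell_map(cell_map: CellMap, path) -> None:
    """Write a :class:`CellMap`; rows sorted by cell_id for determinism."""
    path = Path(path)
    cells = cell_map.cells.sort_values("cell_id", kind="stable")
    out = pd.DataFrame(
        {
            "slide_id": cell_map.slide_id,
            "patient_id": cell_map.patient_id,
            "cell_id": cells["cell_id"].to_numpy(),
            "x_px": cells["x"].to_numpy(),
            "y_px": cells["y"].to_numpy(),
            "cell_type": cells["cell_type"].to_numpy(),
        }
    )
    meta = (
        f"#meta: slide_id={cell_map.slide_id},patient_id={cell_map.patient_id},"
        f"width_px={cell_map.width_px},height_px={cell_map.height_px},"
        f"microns_per_pixel={cell_map.microns_per_pixel}\n"
    )
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(meta)
        out.to_csv(fh, index=False, lineterminator="\n")


def read_clinical(path) -> pd.DataFrame:
    """Read a per-patient clinical table.

    Returns a DataFrame with one row per patient: ``os_months`` (float >= 0),
    ``event`` / ``tki_treated`` / ``surgery`` in {0, 1}, ``egfr_class`` in
    {sensitizing, other}, plus ``age``, ``sex``, ``smoking_status``. Empty
    fields become NaN/None (explicit missing); categorical vocabularies are
    enforced.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, header row is mandatory") from None
    _require_columns(df, _CLINICAL_COLUMNS, path)
    df = df.replace({"": None})
    out = pd.DataFrame({"patient_id": df["patient_id"]})
    out["os_months"] = pd.to_numeric(df["os_months"], errors="raise").astype(float)
    if (out["os_months"] < 0).any():
        row = int(np.flatnonzero((out["os_months"] < 0).to_numpy())[0])
        raise ValidationError(f"{path}: negative os_months at data row {row + 1}")
    for col in ("event", "tki_treated", "surgery"):
        vals = pd.to_numeric(df[col], errors="raise")
        bad = ~vals.isin([0, 1]) & vals.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: {col} must be 0 or 1, got {vals.iloc[row]!r} at data row {row + 1}"
            )
        out[col] = vals.astype("Int64")
    bad = df["egfr_class"].notna() & ~df["egfr_class"].isin(EGFR_CLASSES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: egfr_class must be one of {EGFR_CLASSES}, got "
            f"{df['egfr_class'].iloc[row]!r} at data row {row + 1}"
        )
    out["egfr_class"] = df["egfr_class"]
    out["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
    out["sex"] = df["sex"]
    out["smoking_status"] = df["smoking_status"]
    if out["patient_id"].duplicated().any():
        dup = out.loc[out["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate patient_id {dup!r}")
    return out


def write_clinical(cohort: pd.DataFrame, path) -> None:
    cohort = cohort[_CLINICAL_COLUMNS]
    cohort.to_csv(path, index=False, lineterminator="\n")


def read_expression(path) -> pd.DataFrame:
    """Read a gene x patient expression matrix (TSV, first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene symbol {dup!r}")
    if (df.to_numpy(float) < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in standard GMT (name, description, members; tab-separated).

    Duplicate member symbols within a set are dropped (first occurrence kept);
    duplicate set names across lines are an error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            name = name.strip()
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(g.strip() for g in genes if g.strip()))
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
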