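"""Image-genomic association: Spearman gene rankings and preranked GSEA.

Genes are first filtered by zero fraction (a gene expressed as 0 in more
than 20% of patients is removed), then correlated with an image feature
(e.g. the tumor-stroma interaction fraction) by Spearman rank correlation.
The rho-ordered gene list feeds a preranked gene-set enrichment analysis:
the enrichment score (ES) is the signed extremum of the weighted
Kolmogorov-Smirnov running sum (weight |rho|^exponent, exponent 1 by
default); the null is built by drawing random same-size gene sets, and
p-values use +1 smoothing over sign-matched null scores. Benjamini-Hochberg
adjustment is applied across gene sets within one analysis. A patient-ID
shuffle rerun serves as the negative control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

#: Marker panels used to summarize expression along an image feature.
MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "fibroblast_angiogenesis": ("ACTA2", "PECAM1"),
    "hgf_arm": ("HGF", "MET"),
    "egfr_arm": ("EGFR", "ERBB3"),
    "shared_pi3k": ("GAB1", "GRB2", "PIK3R1", "PIK3CA"),
    "mesenchymal": ("VIM", "TGFB1", "FGFR1", "ZEB1"),
    "epithelial": ("CDH1", "CTNNA1", "JUP"),
}


def filter_genes(expr: pd.DataFrame, max_zero_fraction: float = 0.20) -> pd.DataFrame:
    """Drop genes whose expression is 0 in more than ``max_zero_fraction`` of patients."""
    if expr.empty:
        raise ValueError("empty expression matrix")
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must lie in [0, 1]")
    zero_frac = (expr == 0).sum(axis=1) / expr.shape[1]
    return expr.loc[zero_frac <= max_zero_fraction]


@dataclass(frozen=True)
class GeneRanking:
    """Per-gene Spearman correlation with one image feature, rho-descending."""

    feature: str
    table: pd.DataFrame = field(repr=False)  # index gene; columns rho, p
    n_patients: int = 0
    excluded_constant: tuple = ()

    @property
    def genes(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def rho(self) -> np.ndarray:
        return self.table["rho"].to_numpy()


def rank_genes(expr: pd.DataFrame, feature_values: pd.Series, feature_name: str = "feature") -> GeneRanking:
    """Spearman rho (average-rank ties) of every gene against the feature.

    Patients are aligned by id; zero-variance genes are excluded and flagged.
    Per-gene p uses the large-sample t approximation.
    """
    common = expr.columns.intersection(feature_values.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 common patients, got {len(common)}")
    X = expr[common].to_numpy(float)
    f = feature_values[common].to_numpy(float)
    n = len(common)

    const = X.std(axis=1) == 0
    if const.any():
        logger.warning("excluding %d constant genes from the ranking", int(const.sum()))
    genes = expr.index.to_numpy()[~const]
    R = stats.rankdata(X[~const], axis=1, method="average")
    rf = stats.rankdata(f, method="average")
    Rc = R - R.mean(axis=1, keepdims=True)
    rfc = rf - rf.mean()
    denom = np.sqrt((Rc**2).sum(axis=1) * (rfc**2).sum())
    rho = (Rc @ rfc) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |rho| == 1 -> p = 0 in the t approximation
    tab = pd.DataFrame({"rho": rho, "p": p}, index=genes).sort_values(
        "rho", ascending=False, kind="stable"
    )
    return GeneRanking(
        feature=feature_name,
        table=tab,
        n_patients=n,
        excluded_constant=tuple(expr.index.to_numpy()[const]),
    )


def enrichment_score(
    rho_sorted: np.ndarray, member_mask: np.ndarray, exponent: float = 1.0
) -> tuple[float, int]:
    """Weighted KS enrichment score of one gene set over a rho-ordered list.

    Returns (ES, index of the running-sum extremum). The running sum gains
    |rho_i|^exponent (normalized) at member genes and loses 1/(N - m) at
    non-members; ES is the value of largest magnitude.
    """
    N = len(rho_sorted)
    m = int(member_mask.sum())
    if m == 0 or m == N:
        raise ValueError("gene set must be a proper nonempty subset of the ranking")
    w = np.abs(rho_sorted) ** exponent
    hit = np.where(member_mask, w, 0.0)
    total = hit.sum()
    if total == 0:  # all member rhos exactly zero: fall back to unweighted hits
        hit = member_mask.astype(float)
        total = float(m)
    running = np.cumsum(hit / total - (~member_mask) / (N - m))
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), i_ext


def _es_null_batch(
    rho_sorted: np.ndarray, positions: np.ndarray, exponent: float
) -> np.ndarray:
    """ES for a batch of random same-size sets given by sorted hit positions.

    Exploits that the running sum is piecewise linear with breaks at the hit
    positions, so its extrema occur immediately before or after a hit.
    ``positions`` is (B, m), each row ascending.
    """
    N = len(rho_sorted)
    B, m = positions.shape
    w = np.abs(rho_sorted) ** exponent
    w_hits = w[positions]  # (B, m)
    total = w_hits.sum(axis=1, keepdims=True)
    total = np.where(total == 0, 1.0, total)
    cumw = np.cumsum(w_hits, axis=1) / total
    j = np.arange(1, m + 1)
    miss_step = 1.0 / (N - m)
    after = cumw - (positions + 1 - j) * miss_step
    before = (cumw - w_hits / total) - (positions - (j - 1)) * miss_step
    cand = np.concatenate([after, before], axis=1)
    i_ext = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), i_ext]


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's enrichment against a gene ranking."""

    set_name: str
    size: int
    es: float
    nes: float
    p_value: float
    p_adjusted: float
    leading_edge: tuple


def preranked_gsea(
    ranking: GeneRanking,
    sets: GeneSetCollection,
    n_permutations: int = 10000,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA of every gene set against the rho-ordered gene list.

    The permutation null draws random gene sets of the same size from the
    ranked universe; p = (b + 1) / (n + 1) over sign-matched null scores with
    b the count of null ES at least as extreme in magnitude. NES divides ES
    by the mean magnitude of sign-matched null scores. BH adjustment is
    applied across the tested sets. Deterministic given ``seed``.
    """
    usable = sets.filtered(ranking.genes, min_size, max_size)
    if len(usable) == 0:
        logger.warning("no gene sets survive size filtering [%d, %d]", min_size, max_size)
        return pd.DataFrame(
            columns=["set", "size", "es", "nes", "p", "p_adjusted", "leading_edge"]
        ).set_index("set")
    rho = ranking.rho
    genes = ranking.genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    rng = np.random.default_rng(seed)

    # shared null per set size: permutation ES for random same-size sets
    sizes = sorted({len(members) for _, members in usable})
    null_by_size: dict[int, np.ndarray] = {}
    for m in sizes:
        idx = np.argsort(rng.random((n_permutations, N)), axis=1)[:, :m]  # random m-subsets
        null_by_size[m] = _es_null_batch(rho, np.sort(idx, axis=1), weight_exponent)

    rows = []
    for name, members in usable:
        mask = np.zeros(N, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        es, i_ext = enrichment_score(rho, mask, weight_exponent)
        null = null_by_size[len(members)]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        b = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (b + 1) / (n_same + 1)
        mean_mag = np.abs(null[same_sign]).mean() if n_same else np.nan
        nes = es / mean_mag if n_same and mean_mag > 0 else np.nan
        if es >= 0:
            le = tuple(genes[: i_ext + 1][mask[: i_ext + 1]])
        else:
            le = tuple(genes[i_ext:][mask[i_ext:]])
        rows.append(
            {"set": name, "size": len(members), "es": es, "nes": nes, "p": p,
             "leading_edge": le}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out[["size", "es", "nes", "p", "p_adjusted", "leading_edge"]]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def shuffle_control(
    expr: pd.DataFrame,
    feature_values: pd.Series,
    sets: GeneSetCollection,
    seed: int = 0,
    feature_name: str = "feature",
    **gsea_kwargs,
) -> pd.DataFrame:
    """Negative control: permute patient IDs of the feature, rerun ranking + GSEA."""
    rng = np.random.default_rng(seed)
    shuffled = pd.Series(
        rng.permutation(feature_values.to_numpy()), index=feature_values.index
    )
    ranking = rank_genes(expr, shuffled, feature_name=f"{feature_name}_shuffled")
    return preranked_gsea(ranking, sets, seed=seed, **gsea_kwargs)


def marker_panel_summary(
    expr: pd.DataFrame,
    feature_values: pd.Series,
    panels: dict[str, tuple[str, ...]] | None = None,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Mean standardized expression of panel genes across feature-quantile bins.

    Patients are binned by feature quantile (bin 0 = lowest feature values);
    each panel gene contributes its per-bin mean z-scored expression plus its
    Spearman rho and p against the feature. Panel genes absent from the
    matrix are reported in the log, not fatal.
    """
    panels = MARKER_PANELS if panels is None else panels
    common = expr.columns.intersection(feature_values.index)
    if n_bins > len(common):
        raise ValueError(f"n_bins={n_bins} exceeds patient count {len(common)}")
    f = feature_values[common]
    bins = pd.qcut(f.rank(method="first"), q=n_bins, labels=False)
    rows = []
    for panel, genes in panels.items():
        for g in genes:
            if g not in expr.index:
                logger.warning("panel %s: gene %s absent from expression matrix", panel, g)
                continue
            vals = expr.loc[g, common].astype(float)
            sd = vals.std(ddof=0)
            z = (vals - vals.mean()) / sd if sd > 0 else vals * 0.0
            rho, p = stats.spearmanr(f.to_numpy(), vals.to_numpy())
            row = {"panel": panel, "gene": g, "rho": rho, "p": p}
            for b in range(n_bins):
                row[f"bin_{b}"] = float(z[bins.to_numpy() == b].mean())
            rows.append(row)
    return pd.DataFrame(rows)
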