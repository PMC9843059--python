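"""Synthetic data with the statistical structure the pipeline assumes.

Three generators, all pure functions of (params, seed):

* :func:`simulate_cell_map` — marked spatial point patterns: tumor nuclei as
  Poisson clusters around circular nests, stroma as a background process with
  a mixing fraction ``theta`` relocated into the nests (theta = 0 pure nests,
  theta = 1 fully mixed), the remaining four types as sparse background.
* :func:`simulate_cohort` — exponential proportional-hazards survival from a
  linear predictor over the 12 image features, with a treatment term whose
  log-hazard may depend on the patient's true benefit group (effect
  modification), and independent exponential censoring.
* :func:`simulate_expression` — a gene x patient matrix in which planted
  genes track an image feature through a Gaussian copula calibrated to a
  target Spearman rho, plus independent null genes, packaged with planted
  and decoy gene sets.

A direct per-patient feature-table generator (:func:`simulate_features`)
supports cohort-scale studies without re-running the image pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CELL_TYPES, CellMap, GeneSetCollection
from .features import DENSITY_FEATURES, INTERACTION_FEATURES, FEATURE_NAMES


# ---------------------------------------------------------------------------
# cell maps


@dataclass(frozen=True)
class CellMapSimParams:
    """Marked-point-pattern parameters for one synthetic slide.

    Intensities are expected cells per pixel^2 over the whole slide; tumor
    intensity applies within nest discs only. ``theta`` is the fraction of
    stroma relocated from the background into tumor nests.
    """

    width_px: int = 4000
    height_px: int = 4000
    n_tumor_nests: int = 4
    nest_radius_px: float = 500.0
    tumor_intensity_in_nest: float = 2.0e-3
    stroma_intensity: float = 5.0e-5
    other_intensity: float = 1.0e-5  # each of lymphocyte/red_blood_cell/macrophage/karyorrhexis
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide extent must be positive")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        for name in ("tumor_intensity_in_nest", "stroma_intensity", "other_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _uniform_in_disc(rng: np.random.Generator, center, radius, n) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)])


def simulate_cell_map(
    params: CellMapSimParams, seed: int, slide_id: str = "S1", patient_id: str = "P1"
) -> CellMap:
    """Generate one slide's nuclei map; reproducible given ``seed``."""
    rng = np.random.default_rng(seed)
    W, H, R = params.width_px, params.height_px, params.nest_radius_px
    margin = min(R, W / 2 - 1, H / 2 - 1)
    centers = np.column_stack(
        [
            rng.uniform(margin, W - margin, size=params.n_tumor_nests),
            rng.uniform(margin, H - margin, size=params.n_tumor_nests),
        ]
    )
    nest_area = np.pi * R**2
    xs, ys, types = [], [], []

    # tumor: Poisson cluster in each nest disc
    for c in centers:
        n = rng.poisson(params.tumor_intensity_in_nest * nest_area)
        pts = _uniform_in_disc(rng, c, R, n)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        types.append(np.full(n, "tumor"))

    def _outside_nests(pts: np.ndarray) -> np.ndarray:
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return (d2 > R**2).all(axis=1)

    # stroma: background outside nests, fraction theta relocated into nests
    n_stroma = rng.poisson(params.stroma_intensity * W * H)
    in_nest = rng.uniform(size=n_stroma) < params.theta
    n_in = int(in_nest.sum())
    if n_in:
        which = rng.integers(0, params.n_tumor_nests, size=n_in)
        pts_in = np.concatenate(
            [
                _uniform_in_disc(rng, centers[k], R, int((which == k).sum()))
                for k in range(params.n_tumor_nests)
            ]
        )
        xs.append(pts_in[:, 0])
        ys.append(pts_in[:, 1])
        types.append(np.full(n_in, "stroma"))
    n_out = n_stroma - n_in
    kept: list[np.ndarray] = []
    total = 0
    while total < n_out:  # rejection-sample the outside-nest background
        cand = np.column_stack(
            [rng.uniform(0, W, size=2 * n_out + 8), rng.uniform(0, H, size=2 * n_out + 8)]
        )
        cand = cand[_outside_nests(cand)]
        kept.append(cand)
        total += len(cand)
    if n_out:
        pts_out = np.concatenate(kept)[:n_out]
        xs.append(pts_out[:, 0])
        ys.append(pts_out[:, 1])
        types.append(np.full(n_out, "stroma"))

    # sparse uniform background for the remaining four types
    for t in ("lymphocyte", "red_blood_cell", "macrophage", "karyorrhexis"):
        n = rng.poisson(params.other_intensity * W * H)
        xs.append(rng.uniform(0, W, size=n))
        ys.append(rng.uniform(0, H, size=n))
        types.append(np.full(n, t))

    x = np.clip(np.concatenate(xs), 0, np.nextafter(W, 0))
    y = np.clip(np.concatenate(ys), 0, np.nextafter(H, 0))
    tt = np.concatenate(types)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(len(x))],
            "x": x,
            "y": y,
            "cell_type": tt,
        }
    )
    return CellMap(
        slide_id=slide_id,
        patient_id=patient_id,
        width_px=W,
        height_px=H,
        cells=cells,
    )


# ---------------------------------------------------------------------------
# per-patient feature tables


def simulate_features(n_patients: int, seed: int) -> pd.DataFrame:
    """Per-patient 12-feature table with realistic scales and correlations.

    Interaction fractions are Dirichlet-distributed (sum to 1, negatively
    correlated, tumor-tumor dominant as on tumor-rich slides); densities are
    independent gamma counts. Index is the patient id.
    """
    rng = np.random.default_rng(seed)
    # mean composition: tumor .55, stroma .15, lymphocyte .15, rbc/mac/kary .05
    alpha = np.array([0.55, 0.15, 0.15, 0.05, 0.05, 0.05]) * 30.0
    inter = rng.dirichlet(alpha, size=n_patients)
    dens_means = np.array([400.0, 100.0, 80.0, 30.0, 20.0, 20.0])
    shape = 1 / 0.4**2  # CV 0.4
    dens = rng.gamma(shape, dens_means / shape, size=(n_patients, 6))
    df = pd.DataFrame(
        np.column_stack([dens, inter]),
        columns=list(DENSITY_FEATURES) + list(INTERACTION_FEATURES),
        index=[f"P{i:04d}" for i in range(n_patients)],
    )
    return df[list(FEATURE_NAMES)]


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSimParams:
    """Exponential proportional-hazards cohort generator settings.

    ``beta`` maps feature name -> log-hazard per unit of the feature (an
    interaction fraction planted at per-10% HR h has beta = ln(h) / 0.1).
    ``treatment_log_hr`` is the homogeneous treatment effect;
    ``benefit_log_hr`` / ``nonbenefit_log_hr``, when set, modify the
    treatment effect by the patient's true group (linear predictor below /
    above its cohort median).
    """

    beta: dict = field(default_factory=dict)
    baseline_rate: float = 0.03  # events per month; median OS ~ 23 months
    censoring_rate: float = 0.01
    treat_fraction: float = 0.5
    treatment_log_hr: float = 0.0
    benefit_log_hr: float | None = None
    nonbenefit_log_hr: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        unknown = set(self.beta) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features in beta: {sorted(unknown)}")


def per10_log_hr(per10_hr: float) -> float:
    """Log-hazard per unit (0-1 scale) for a stated per-10% hazard ratio."""
    return float(np.log(per10_hr) / 0.1)


def simulate_cohort(
    features: pd.DataFrame, params: CohortSimParams, seed: int
) -> pd.DataFrame:
    """Survival, treatment and covariates for the patients in ``features``.

    Returns a clinical table (core dialect columns plus ``true_group``):
    exponential event times with hazard
    ``baseline_rate * exp(beta' f + treatment term)``, independent
    exponential censoring, Bernoulli treatment assignment.
    """
    rng = np.random.default_rng(seed)
    n = len(features)
    lp = np.zeros(n)
    for name, b in params.beta.items():
        lp += b * features[name].to_numpy(float)
    lp = lp - lp.mean()  # center: baseline_rate is the typical-patient hazard

    treated = (rng.uniform(size=n) < params.treat_fraction).astype(int)
    benefit_group = lp <= np.median(lp)  # low linear predictor = predicted to benefit
    t_eff = np.full(n, params.treatment_log_hr)
    if params.benefit_log_hr is not None:
        t_eff[benefit_group] = params.benefit_log_hr
    if params.nonbenefit_log_hr is not None:
        t_eff[~benefit_group] = params.nonbenefit_log_hr
    hazard = params.baseline_rate * np.exp(lp + treated * t_eff)
    t_event = rng.exponential(1.0 / hazard)
    if params.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / params.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_months = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    age = rng.normal(62, 9, size=n).round(1)
    sex = rng.choice(["female", "male"], size=n)
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.55, 0.3, 0.15])
    surgery = (rng.uniform(size=n) < 0.3).astype(int)
    egfr = rng.choice(["sensitizing", "other"], size=n, p=[0.8, 0.2])
    return pd.DataFrame(
        {
            "patient_id": features.index.to_numpy(),
            "os_months": os_months,
            "event": event,
            "tki_treated": treated,
            "egfr_class": egfr,
            "age": age,
            "sex": sex,
            "smoking_status": smoking,
            "surgery": surgery,
            "true_group": np.where(benefit_group, "benefit", "nonbenefit"),
        }
    )


def simulate_interaction_cohort(
    n_patients: int,
    benefit_treatment_hr: float = 1.0,
    nonbenefit_treatment_hr: float = 1.0,
    baseline_rate: float = 0.03,
    censoring_rate: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort with known benefit/non-benefit groups for interaction-test studies.

    Groups are assigned 50/50; treatment multiplies the hazard by
    ``benefit_treatment_hr`` in the benefit group and
    ``nonbenefit_treatment_hr`` in the other. Equal HRs give the null of no
    treatment-by-group interaction.
    """
    rng = np.random.default_rng(seed)
    n = n_patients
    group = np.where(np.arange(n) % 2 == 0, "benefit", "nonbenefit")
    treated = (rng.uniform(size=n) < 0.5).astype(int)
    log_hr = np.where(group == "benefit", np.log(benefit_treatment_hr), np.log(nonbenefit_treatment_hr))
    hazard = baseline_rate * np.exp(treated * log_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = (
        rng.exponential(1.0 / censoring_rate, size=n)
        if censoring_rate > 0
        else np.full(n, np.inf)
    )
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "os_months": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
            "tki_treated": treated,
            "egfr_class": rng.choice(["sensitizing", "other"], size=n, p=[0.8, 0.2]),
            "age": rng.normal(62, 9, size=n).round(1),
            "sex": rng.choice(["female", "male"], size=n),
            "smoking_status": rng.choice(
                ["never", "former", "current"], size=n, p=[0.55, 0.3, 0.15]
            ),
            "surgery": (rng.uniform(size=n) < 0.3).astype(int),
            "group": group,
        }
    )


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionSimParams:
    """Planted-correlation expression generator settings.

    ``n_correlated`` genes track the driving image feature with target
    Spearman ``rho``; the remainder are independent. The planted gene set
    contains correlated genes only; ``n_decoy_sets`` same-size sets are drawn
    from null genes.
    """

    n_genes: int = 500
    n_correlated: int = 20
    rho: float = 0.6
    set_size: int = 20
    n_decoy_sets: int = 40
    zero_inflated_fraction: float = 0.05
    seed_gene_prefix: str = "G"

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if self.n_correlated < self.set_size:
            raise ValueError("planted set larger than the correlated block")
        if self.n_correlated > self.n_genes:
            raise ValueError("n_correlated exceeds n_genes")


def _copula_loading(rho_s: float) -> float:
    # Gaussian-copula latent Pearson correlation achieving Spearman rho_s
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def simulate_expression(
    feature_values: pd.Series, params: ExpressionSimParams, seed: int
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Gene x patient matrix plus planted/decoy gene sets.

    Correlated genes are monotone (exponential) transforms of a latent
    Gaussian ``a * z_f + sqrt(1 - a^2) * eps`` where ``z_f`` is the normal
    score of the feature ranks and ``a`` solves the Gaussian-copula relation
    ``rho_s = (6 / pi) * arcsin(a / 2)``; Spearman correlation is invariant
    under the transform, so the target rho is hit up to sampling noise.
    Values are nonnegative (log-normal scale); a small fraction of null genes
    is zero-inflated to exercise the zero-fraction filter.
    """
    if len(feature_values) < 10:
        raise ValueError("need >= 10 patients")
    rng = np.random.default_rng(seed)
    n_pat = len(feature_values)
    ranks = pd.Series(feature_values).rank(method="average").to_numpy()
    from scipy.stats import norm

    z_f = norm.ppf((ranks - 0.5) / n_pat)
    a = _copula_loading(params.rho)
    genes = [f"{params.seed_gene_prefix}{i:04d}" for i in range(params.n_genes)]
    z = np.empty((params.n_genes, n_pat))
    eps = rng.standard_normal((params.n_genes, n_pat))
    z[: params.n_correlated] = a * z_f[None, :] + np.sqrt(1 - a**2) * eps[: params.n_correlated]
    z[params.n_correlated :] = eps[params.n_correlated :]
    expr = np.exp(z)  # log-normal expression scale, strictly positive

    n_null = params.n_genes - params.n_correlated
    n_zi = int(round(params.zero_inflated_fraction * n_null))
    if n_zi:
        zi_rows = params.n_correlated + rng.choice(n_null, size=n_zi, replace=False)
        for r in zi_rows:
            # zero in ~30% of patients: removed by the default 20% filter
            mask = rng.uniform(size=n_pat) < 0.3
            expr[r, mask] = 0.0

    mat = pd.DataFrame(expr, index=genes, columns=feature_values.index)
    planted = tuple(genes[: params.set_size])
    sets = {"PLANTED": planted}
    null_genes = np.array(genes[params.n_correlated :])
    for k in range(params.n_decoy_sets):
        members = rng.choice(null_genes, size=params.set_size, replace=False)
        sets[f"DECOY_{k:03d}"] = tuple(sorted(members))
    return mat, GeneSetCollection(sets, {"PLANTED": "planted correlated set"})
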