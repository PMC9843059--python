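"""Elastic-net Cox survival-benefit model and validation statistics.

The core object pair follows the fitted-model convention of statistical
packages: :class:`BenefitCoxModel` holds the aligned feature matrix and
clinical table; :meth:`BenefitCoxModel.fit` runs an elastic-net penalized Cox
regression of overall survival on the 12 image features (treated patients
only) and returns :class:`BenefitCoxResults`, which carries the selected
coefficients, scores new patients (risk = sum of feature x coefficient, so a
higher score means predicted-not-to-benefit), performs the cohort-median
split, and serializes to a plain-text document.

The penalty path comes from scikit-survival's coordinate-descent coxnet; the
penalty strength is chosen by k-fold cross-validated partial likelihood
(Verweij-van Houwelingen deviance, Breslow ties — the same objective coxnet
optimizes). Features are standardized internally; reported coefficients are
rescaled to the original feature units.

Validation statistics (Kaplan-Meier / log-rank, univariate hazard ratios,
and the treatment-by-group interaction Cox model with clinical adjusters)
are thin, validated wrappers over lifelines (Efron ties, Wald intervals).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .features import FEATURE_NAMES, INTERACTION_FEATURES

logger = logging.getLogger(__name__)

BENEFIT = "predicted_to_benefit"
NONBENEFIT = "predicted_not_to_benefit"


def cox_breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow-ties Cox log partial likelihood of a fixed linear predictor."""
    order = np.argsort(time, kind="stable")
    t, e, l = time[order], event[order].astype(float), lp[order]
    rev = np.logaddexp.accumulate(l[::-1])[::-1]  # rev[i] = log sum_{j >= i} exp(l_j)
    _, first = np.unique(t, return_index=True)
    sum_lp_ev = np.add.reduceat(l * e, first)
    d = np.add.reduceat(e, first)
    return float(np.sum(sum_lp_ev - d * rev[first]))


@dataclass
class BenefitCoxModel:
    """Penalized Cox model of TKI survival benefit on the 12 image features.

    Parameters
    ----------
    features : DataFrame indexed by patient id with the 12 feature columns.
    cohort : clinical table with patient_id, os_months, event (and optionally
        tki_treated for :meth:`from_dataframes` restriction).
    """

    features: pd.DataFrame
    cohort: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        cohort = self.cohort.set_index("patient_id") if "patient_id" in self.cohort else self.cohort
        common = self.features.index.intersection(cohort.index)
        if len(common) < 2:
            raise ValueError("need >= 2 patients common to features and cohort")
        self.cohort = cohort.loc[common]
        self.features = self.features.loc[common, list(FEATURE_NAMES)]
        if int(self.cohort["event"].sum()) < 2:
            raise ValueError("need >= 2 observed events to fit a Cox model")

    @classmethod
    def from_dataframes(
        cls, features: pd.DataFrame, cohort: pd.DataFrame, treated_only: bool = True
    ) -> "BenefitCoxModel":
        """Build from tidy tables, optionally restricting to TKI-treated patients."""
        if treated_only:
            cohort = cohort[cohort["tki_treated"] == 1]
        return cls(features=features, cohort=cohort)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        l1_ratio: float = 0.5,
        cv_folds: int = 5,
        seed: int = 0,
        alpha: float | None = None,
        lambda_rule: str = "min",
        n_alphas: int = 50,
    ) -> "BenefitCoxResults":
        """Fit the elastic-net Cox model.

        ``alpha=None`` selects the penalty strength by ``cv_folds``-fold
        cross-validated partial-likelihood deviance (rule ``"min"`` or the
        sparser ``"1se"``); a float fixes it. Deterministic given ``seed``.
        """
        X = self.features.to_numpy(float)
        time = self.cohort["os_months"].to_numpy(float)
        event = self.cohort["event"].to_numpy(int)
        y = Surv.from_arrays(event=event.astype(bool), time=time)

        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        constant = std == 0
        if constant.any():
            dropped = [n for n, c in zip(FEATURE_NAMES, constant) if c]
            logger.warning("dropping constant features: %s", dropped)
        std_safe = np.where(constant, 1.0, std)
        Z = (X - mean) / std_safe
        Z[:, constant] = 0.0

        cv_path = None
        if alpha is None:
            base = CoxnetSurvivalAnalysis(
                l1_ratio=l1_ratio, n_alphas=n_alphas, alpha_min_ratio=0.01, normalize=False
            )
            base.fit(Z, y)
            alphas = np.asarray(base.alphas_)
            if cv_folds > len(Z):
                logger.warning(
                    "cv_folds=%d exceeds cohort size %d; reduced", cv_folds, len(Z)
                )
                cv_folds = max(2, len(Z) // 2)
            folds = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            dev = np.zeros((cv_folds, len(alphas)))
            for k, (tr, _te) in enumerate(folds.split(Z)):
                fold_fit = CoxnetSurvivalAnalysis(
                    l1_ratio=l1_ratio, alphas=alphas, normalize=False
                )
                fold_fit.fit(Z[tr], y[tr])
                coefs = fold_fit.coef_  # (p, n_fit_alphas)
                fit_alphas = np.asarray(fold_fit.alphas_)
                for j, a in enumerate(alphas):
                    jj = int(np.argmin(np.abs(fit_alphas - a)))
                    beta = coefs[:, jj]
                    ll_full = cox_breslow_loglik(Z @ beta, time, event)
                    ll_train = cox_breslow_loglik(Z[tr] @ beta, time[tr], event[tr])
                    dev[k, j] = -2.0 * (ll_full - ll_train)
            # center each fold on its null-model (largest-alpha) deviance so the
            # SE tracks fold-to-fold variation in *improvement*, not in the
            # absolute deviance level of the fold's test split
            dev = dev - dev[:, [0]]
            mean_dev = dev.mean(axis=0)
            se_dev = dev.std(axis=0, ddof=1) / np.sqrt(cv_folds)
            i_min = int(np.argmin(mean_dev))
            if lambda_rule == "min":
                alpha = float(alphas[i_min])
            elif lambda_rule == "1se":
                within = mean_dev <= mean_dev[i_min] + se_dev[i_min]
                alpha = float(alphas[np.flatnonzero(within)[0]])  # alphas descend
            else:
                raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
            cv_path = pd.DataFrame(
                {"alpha": alphas, "mean_deviance": mean_dev, "se_deviance": se_dev}
            )

        final = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio,
            alphas=[alpha],
            normalize=False,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            # an all-zero fit is a legitimate outcome at strong penalties
            warnings.filterwarnings("ignore", message="all coefficients are zero")
            final.fit(Z, y)
        beta_std = final.coef_[:, 0]
        beta_std = np.where(constant, 0.0, beta_std)
        beta_orig = beta_std / std_safe
        return BenefitCoxResults(
            model=self,
            coefficients=pd.Series(beta_orig, index=list(FEATURE_NAMES)),
            coefficients_std=pd.Series(beta_std, index=list(FEATURE_NAMES)),
            feature_means=pd.Series(mean, index=list(FEATURE_NAMES)),
            feature_stds=pd.Series(std, index=list(FEATURE_NAMES)),
            alpha=float(alpha),
            l1_ratio=float(l1_ratio),
            cv_folds=int(cv_folds),
            seed=int(seed),
            cv_path=cv_path,
        )


@dataclass
class BenefitCoxResults:
    """Fitted elastic-net Cox benefit model.

    ``coefficients`` are on the original feature scale, so a patient's risk
    score is the plain dot product with the raw feature vector; zero means
    the feature was not selected at the chosen penalty.
    """

    model: BenefitCoxModel | None
    coefficients: pd.Series
    coefficients_std: pd.Series
    feature_means: pd.Series
    feature_stds: pd.Series
    alpha: float
    l1_ratio: float
    cv_folds: int
    seed: int
    cv_path: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def selected_features(self) -> list[str]:
        return [n for n, b in self.coefficients.items() if b != 0.0]

    def predict_risk(self, features: pd.DataFrame) -> pd.Series:
        """Risk score = sum_j beta_j f_j; higher = predicted-not-to-benefit."""
        missing = [c for c in FEATURE_NAMES if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        X = features[list(FEATURE_NAMES)].to_numpy(float)
        return pd.Series(X @ self.coefficients.to_numpy(), index=features.index, name="risk_score")

    def per10_hazard_ratio(self, feature: str) -> float:
        """HR for a 10-percentage-point increase of an interaction fraction."""
        if feature not in INTERACTION_FEATURES:
            raise ValueError(
                f"per-10% convention is defined for interaction fractions only, got {feature!r}"
            )
        return float(np.exp(0.1 * self.coefficients[feature]))

    def summary(self) -> pd.DataFrame:
        """Per-feature coefficient table; per-10% HR for interaction fractions."""
        rows = []
        for name in FEATURE_NAMES:
            b = self.coefficients[name]
            rows.append(
                {
                    "feature": name,
                    "coef": b,
                    "coef_standardized": self.coefficients_std[name],
                    "selected": b != 0.0,
                    "per10_hr": np.exp(0.1 * b) if name in INTERACTION_FEATURES else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("feature")

    # -- persistence (plain-text key-value document) ------------------------

    def save(self, path) -> None:
        lines = [
            "# tmepipe risk model",
            f"l1_ratio={float(self.l1_ratio)!r}",
            f"alpha={float(self.alpha)!r}",
            f"cv_folds={self.cv_folds}",
            f"seed={self.seed}",
        ]
        for name in FEATURE_NAMES:
            lines.append(
                f"feature\t{name}\tcoef={float(self.coefficients[name])!r}"
                f"\tcoef_std={float(self.coefficients_std[name])!r}"
                f"\tmean={float(self.feature_means[name])!r}\tstd={float(self.feature_stds[name])!r}"
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path) -> "BenefitCoxResults":
        kv: dict[str, float] = {}
        feats: dict[str, dict[str, float]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line or line.startswith("#"):
                continue
            if line.startswith("feature\t"):
                _, name, *pairs = line.split("\t")
                feats[name] = {k: float(v) for k, v in (p.split("=", 1) for p in pairs)}
            else:
                k, v = line.split("=", 1)
                kv[k] = float(v)
        names = list(FEATURE_NAMES)
        return cls(
            model=None,
            coefficients=pd.Series({n: feats[n]["coef"] for n in names}),
            coefficients_std=pd.Series({n: feats[n]["coef_std"] for n in names}),
            feature_means=pd.Series({n: feats[n]["mean"] for n in names}),
            feature_stds=pd.Series({n: feats[n]["std"] for n in names}),
            alpha=kv["alpha"],
            l1_ratio=kv["l1_ratio"],
            cv_folds=int(kv["cv_folds"]),
            seed=int(kv["seed"]),
        )


def fit_penalized_cox(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    l1_ratio: float = 0.5,
    cv_folds: int = 5,
    seed: int = 0,
    alpha: float | None = None,
    lambda_rule: str = "min",
    treated_only: bool = True,
) -> BenefitCoxResults:
    """Functional entry point; see :class:`BenefitCoxModel`."""
    model = BenefitCoxModel.from_dataframes(features, cohort, treated_only=treated_only)
    return model.fit(
        l1_ratio=l1_ratio, cv_folds=cv_folds, seed=seed, alpha=alpha, lambda_rule=lambda_rule
    )


def median_split(scores: pd.Series, threshold: float | None = None) -> pd.DataFrame:
    """Dichotomize risk scores at the cohort median (or a supplied threshold).

    Scores <= threshold are predicted-to-benefit; ties at the median go to the
    benefit group. Returns patient_id-indexed risk_score / group / threshold.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 patients for a median split")
    thr = float(np.median(scores.to_numpy())) if threshold is None else float(threshold)
    group = np.where(scores.to_numpy() <= thr, BENEFIT, NONBENEFIT)
    if (group == BENEFIT).all() and scores.nunique() == 1:
        logger.warning("all risk scores identical; every patient assigned %s", BENEFIT)
    return pd.DataFrame({"risk_score": scores, "group": group, "threshold": thr})


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-group survival contrast: log-rank test plus tidy KM tables."""

    chi_square: float
    p_value: float
    km_table: pd.DataFrame = field(repr=False)  # group, time, at_risk, events, survival
    group_sizes: dict = field(default_factory=dict)


def km_logrank(
    cohort: pd.DataFrame,
    group_col: str,
    time_col: str = "os_months",
    event_col: str = "event",
) -> SurvivalComparison:
    """Two-group log-rank test with Kaplan-Meier curve tables for plotting."""
    groups = cohort[group_col].unique()
    if len(groups) != 2 or (cohort.groupby(group_col).size() == 0).any():
        raise ValueError(f"need exactly two nonempty groups, got {list(groups)}")
    res = multivariate_logrank_test(
        cohort[time_col], cohort[group_col], cohort[event_col]
    )
    tables = []
    for g, sub in cohort.groupby(group_col):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        et = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        tables.append(
            pd.DataFrame(
                {
                    "group": str(g),
                    "time": et.index.to_numpy(float),
                    "at_risk": et["at_risk"].to_numpy(int),
                    "events": et["observed"].to_numpy(int),
                    "survival": surv.reindex(et.index).to_numpy(float),
                }
            )
        )
    return SurvivalComparison(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        km_table=pd.concat(tables, ignore_index=True),
        group_sizes={str(g): int(n) for g, n in cohort.groupby(group_col).size().items()},
    )


@dataclass(frozen=True)
class HazardRatio:
    """Wald hazard ratio for one covariate from a Cox fit (Efron ties)."""

    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    log_hr: float
    se: float
    n: int
    n_events: int
    converged: bool = True

    def per10(self) -> "HazardRatio":
        """Rescale to a 0.1-unit increment (per-10% convention for fractions)."""
        return HazardRatio(
            covariate=self.covariate,
            hr=float(np.exp(0.1 * self.log_hr)),
            ci_low=float(np.exp(0.1 * (self.log_hr - 1.959963984540054 * self.se))),
            ci_high=float(np.exp(0.1 * (self.log_hr + 1.959963984540054 * self.se))),
            p_value=self.p_value,
            log_hr=0.1 * self.log_hr,
            se=0.1 * self.se,
            n=self.n,
            n_events=self.n_events,
            converged=self.converged,
        )


def _encode_covariates(df: pd.DataFrame, cols) -> pd.DataFrame:
    """Numeric passthrough; categoricals to drop-first dummies; complete-case."""
    parts = []
    for c in cols:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).rename(c))
        else:
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def cox_hr(
    cohort: pd.DataFrame,
    covariate: str,
    adjust: tuple = (),
    time_col: str = "os_months",
    event_col: str = "event",
) -> HazardRatio:
    """Cox proportional-hazards HR with Wald 95% CI for one covariate."""
    cols = [covariate, *adjust]
    X = _encode_covariates(cohort, cols)
    data = pd.concat(
        [cohort[[time_col, event_col]].reset_index(drop=True), X.reset_index(drop=True)], axis=1
    ).dropna()
    if data[covariate].nunique() <= 1:
        raise ValueError(f"covariate {covariate!r} is constant")
    if int(data[event_col].sum()) < 1:
        raise ValueError("no observed events")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(data, duration_col=time_col, event_col=event_col)
        except Exception as exc:  # flagged, not fatal: caller sees converged=False
            logger.warning("Cox fit did not converge: %s", exc)
            return HazardRatio(covariate, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                               len(data), int(data[event_col].sum()), converged=False)
    s = cph.summary.loc[covariate]
    return HazardRatio(
        covariate=covariate,
        hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        log_hr=float(s["coef"]),
        se=float(s["se(coef)"]),
        n=len(data),
        n_events=int(data[event_col].sum()),
        converged=converged,
    )


def interaction_cox(
    cohort: pd.DataFrame,
    group_col: str = "group",
    treat_col: str = "tki_treated",
    adjust: tuple = ("age", "sex", "smoking_status", "surgery"),
    time_col: str = "os_months",
    event_col: str = "event",
) -> HazardRatio:
    """Treatment-by-predicted-group interaction in a multivariate Cox model.

    Fits main effects for treatment and group, their product term, and the
    clinical adjusters; constant adjusters are dropped with a warning;
    complete-case on the adjusters. Returns the interaction term's HR.
    """
    df = cohort.copy()
    grp_levels = sorted(df[group_col].astype(str).unique())
    if len(grp_levels) != 2:
        raise ValueError(f"{group_col} must have two levels, got {grp_levels}")
    grp = (df[group_col].astype(str) == grp_levels[1]).astype(float)
    trt = df[treat_col].astype(float)
    cell_counts = pd.crosstab(grp, trt)
    if cell_counts.shape != (2, 2) or (cell_counts == 0).any().any():
        empty = [
            f"(group={grp_levels[int(g)]}, treated={int(t)})"
            for g in (0, 1)
            for t in (0, 1)
            if g not in cell_counts.index
            or t not in cell_counts.columns
            or cell_counts.loc[g].get(t, 0) == 0
        ]
        raise ValueError(f"empty cell(s) in group x treatment table: {empty}")
    usable_adjust = []
    for c in adjust:
        if df[c].nunique(dropna=True) <= 1:
            logger.warning("adjuster %r is constant; dropped", c)
        else:
            usable_adjust.append(c)
    X = pd.DataFrame(
        {"treated": trt.to_numpy(), "group_high": grp.to_numpy()},
        index=df.index,
    )
    X["treated_x_group"] = X["treated"] * X["group_high"]
    if usable_adjust:
        X = pd.concat([X, _encode_covariates(df, usable_adjust)], axis=1)
    data = pd.concat([df[[time_col, event_col]], X], axis=1).dropna()
    n_drop = len(df) - len(data)
    if n_drop:
        logger.warning("complete-case analysis dropped %d patients", n_drop)
    cph = CoxPHFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col=time_col, event_col=event_col)
    s = cph.summary.loc["treated_x_group"]
    return HazardRatio(
        covariate="treated_x_group",
        hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        log_hr=float(s["coef"]),
        se=float(s["se(coef)"]),
        n=len(data),
        n_events=int(data[event_col].sum()),
    )
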