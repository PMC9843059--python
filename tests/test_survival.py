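import numpy as np
import pandas as pd
import pytest

from tmepipe.features import FEATURE_NAMES
from tmepipe.simulate import CohortSimParams, simulate_cohort, simulate_features
from tmepipe.studies import TT, TS, planted_betas
from tmepipe.survival import (
    BENEFIT,
    NONBENEFIT,
    BenefitCoxModel,
    BenefitCoxResults,
    cox_breslow_loglik,
    cox_hr,
    fit_penalized_cox,
    interaction_cox,
    km_logrank,
    median_split,
)


def results_with(coefs: dict) -> BenefitCoxResults:
    beta = pd.Series(0.0, index=list(FEATURE_NAMES))
    for k, v in coefs.items():
        beta[k] = v
    ones = pd.Series(1.0, index=list(FEATURE_NAMES))
    return BenefitCoxResults(
        model=None,
        coefficients=beta,
        coefficients_std=beta.copy(),
        feature_means=ones * 0,
        feature_stds=ones,
        alpha=0.1,
        l1_ratio=0.5,
        cv_folds=5,
        seed=0,
    )


@pytest.fixture(scope="module")
def planted_cohort():
    feats = simulate_features(300, seed=77)
    cohort = simulate_cohort(
        feats, CohortSimParams(beta=planted_betas(), treat_fraction=1.0), seed=78
    )
    return feats, cohort


class TestPenalizedFit:
    def test_infinite_penalty_shrinks_all_to_zero(self, planted_cohort):
        feats, cohort = planted_cohort
        res = fit_penalized_cox(feats, cohort, alpha=1e6, seed=0)
        assert (res.coefficients == 0).all()

    def test_planted_signs_recovered(self, planted_cohort):
        feats, cohort = planted_cohort
        res = fit_penalized_cox(feats, cohort, seed=0, lambda_rule="1se")
        assert res.coefficients[TT] < 0  # tumor-tumor contact is protective
        assert res.coefficients[TS] > 0  # tumor-stroma contact is harmful

    def test_nonzero_count_non_increasing_in_penalty(self, planted_cohort):
        feats, cohort = planted_cohort
        counts = []
        for alpha in (0.001, 0.01, 0.05, 0.2, 1.0):
            res = fit_penalized_cox(feats, cohort, alpha=alpha, seed=0)
            counts.append(len(res.selected_features))
        assert counts == sorted(counts, reverse=True)

    def test_zero_events_rejected(self, planted_cohort):
        feats, cohort = planted_cohort
        dead = cohort.copy()
        dead["event"] = 0
        with pytest.raises(ValueError, match="events"):
            BenefitCoxModel(feats, dead)

    def test_deterministic_given_seed(self, planted_cohort):
        feats, cohort = planted_cohort
        a = fit_penalized_cox(feats, cohort, seed=5)
        b = fit_penalized_cox(feats, cohort, seed=5)
        pd.testing.assert_series_equal(a.coefficients, b.coefficients)

    def test_save_load_round_trip(self, tmp_path, planted_cohort):
        feats, cohort = planted_cohort
        res = fit_penalized_cox(feats, cohort, seed=0)
        p = tmp_path / "model.txt"
        res.save(p)
        back = BenefitCoxResults.load(p)
        pd.testing.assert_series_equal(back.coefficients, res.coefficients)
        assert back.alpha == res.alpha
        pd.testing.assert_series_equal(
            back.predict_risk(feats), res.predict_risk(feats)
        )


class TestScoring:
    def test_all_zero_coefficients_score_zero(self):
        res = results_with({})
        feats = simulate_features(10, seed=1)
        assert (res.predict_risk(feats) == 0).all()

    def test_dot_product_example(self):
        res = results_with({"density_tumor": -1.0, "density_stroma": 2.0})
        feats = simulate_features(1, seed=2)
        feats.loc[:, :] = 0.0
        feats["density_tumor"] = 0.5
        feats["density_stroma"] = 0.25
        assert res.predict_risk(feats).iloc[0] == pytest.approx(0.0)

    def test_linearity(self, rng):
        res = results_with({TT: -3.0, TS: 4.0, "density_tumor": 0.01})
        f = simulate_features(20, seed=3)
        g = simulate_features(20, seed=4)
        g.index = f.index
        lhs = res.predict_risk(f) + res.predict_risk(g)
        rhs = res.predict_risk(f + g)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_missing_feature_rejected(self):
        res = results_with({})
        with pytest.raises(ValueError, match="missing"):
            res.predict_risk(pd.DataFrame({"density_tumor": [1.0]}))

    def test_per10_hazard_ratio_closed_form(self):
        res = results_with({TT: -3.1466})
        assert res.per10_hazard_ratio(TT) == pytest.approx(np.exp(-0.31466))
        assert res.per10_hazard_ratio(TT) == pytest.approx(0.730, abs=5e-4)
        assert results_with({}).per10_hazard_ratio(TS) == 1.0

    def test_per10_rejects_density_features(self):
        with pytest.raises(ValueError, match="interaction"):
            results_with({}).per10_hazard_ratio("density_tumor")


class TestMedianSplit:
    def test_even_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        out = median_split(s)
        assert out["threshold"].iloc[0] == 2.5
        assert (out["group"] == BENEFIT).sum() == 2

    def test_ties_at_median_go_to_benefit(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        out = median_split(s)
        assert out["threshold"].iloc[0] == 2.0
        assert (out["group"] == BENEFIT).sum() == 3
        assert out.loc["d", "group"] == NONBENEFIT

    def test_invariant_under_increasing_transform(self, rng):
        s = pd.Series(rng.normal(size=31))
        base = median_split(s)["group"]
        for f in (np.exp, lambda x: 3 * x + 1, np.arctan):
            trans = median_split(pd.Series(f(s.to_numpy()), index=s.index))["group"]
            assert (base == trans).all()

    def test_group_size_balance(self, rng):
        s = pd.Series(rng.normal(size=50))
        out = median_split(s)
        n_tied = int((s == s.median()).sum())
        sizes = out["group"].value_counts()
        assert abs(sizes.get(BENEFIT, 0) - sizes.get(NONBENEFIT, 0)) <= max(n_tied, 1)

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([1.0]))


class TestLogrank:
    def test_identical_groups_give_null(self):
        df = pd.DataFrame(
            {
                "os_months": [1, 2, 3, 4] * 2,
                "event": [1, 1, 0, 1] * 2,
                "group": ["A"] * 4 + ["B"] * 4,
            }
        )
        res = km_logrank(df, "group")
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_patient_fixture_matches_hand_computation(self):
        # times 1..6, all events, groups ABABAB:
        # O_A - E_A = 3 - (1/2 + 2/5 + 1/2 + 1/3 + 1/2) = 23/30
        # V = 1/4 + 6/25 + 1/4 + 2/9 + 1/4 = 1091/900
        # chi2 = (23/30)^2 / (1091/900) = 529/1091
        df = pd.DataFrame(
            {
                "os_months": [1, 2, 3, 4, 5, 6],
                "event": [1] * 6,
                "group": ["A", "B"] * 3,
            }
        )
        res = km_logrank(df, "group")
        assert res.chi_square == pytest.approx(529 / 1091, rel=1e-9)

    def test_km_table_is_tidy(self, clinical_frame):
        df = clinical_frame.assign(group=np.where(clinical_frame["tki_treated"] == 1, "T", "C"))
        res = km_logrank(df, "group")
        assert set(res.km_table.columns) == {"group", "time", "at_risk", "events", "survival"}
        assert set(res.km_table["group"]) == {"T", "C"}
        assert res.km_table["survival"].between(0, 1).all()

    def test_one_group_rejected(self, clinical_frame):
        df = clinical_frame.assign(group="A")
        with pytest.raises(ValueError):
            km_logrank(df, "group")


class TestCoxHr:
    def _two_arm(self, n, hr, seed):
        rng = np.random.default_rng(seed)
        arm = rng.integers(0, 2, size=n)
        t = rng.exponential(1.0 / (0.05 * hr**arm))
        c = rng.exponential(40.0, size=n)
        return pd.DataFrame(
            {
                "os_months": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "arm": arm,
            }
        )

    def test_recovers_true_hr_two(self):
        # Wald CI coverage of the true HR across replicates, plus unbiasedness
        hrs, cover = [], 0
        n_reps = 30
        for seed in range(n_reps):
            res = cox_hr(self._two_arm(1000, 2.0, seed=seed), "arm")
            hrs.append(res.hr)
            cover += res.ci_low <= 2.0 <= res.ci_high
        assert np.mean(hrs) == pytest.approx(2.0, rel=0.1)
        assert cover / n_reps >= 0.85

    def test_null_covariate_hr_near_one(self):
        df = self._two_arm(2000, 1.0, seed=6)
        res = cox_hr(df, "arm")
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_time_scale_invariance(self):
        df = self._two_arm(300, 2.0, seed=7)
        a = cox_hr(df, "arm")
        doubled = df.assign(os_months=2 * df["os_months"])
        b = cox_hr(doubled, "arm")
        assert a.hr == pytest.approx(b.hr, rel=1e-6)

    def test_constant_covariate_rejected(self):
        df = self._two_arm(50, 1.0, seed=8).assign(flat=1.0)
        with pytest.raises(ValueError, match="constant"):
            cox_hr(df, "flat")

    def test_ci_ordering_and_per10_transform(self):
        df = self._two_arm(500, 2.0, seed=9)
        res = cox_hr(df, "arm")
        assert res.ci_low < res.hr < res.ci_high
        p10 = res.per10()
        assert p10.ci_low < p10.hr < p10.ci_high
        assert p10.hr == pytest.approx(np.exp(0.1 * res.log_hr))


class TestInteractionCox:
    def _cohort(self, seed=0, n=300):
        from tmepipe.simulate import simulate_interaction_cohort

        return simulate_interaction_cohort(n, 0.3, 1.0, seed=seed)

    def test_detects_group_restricted_benefit(self):
        res = interaction_cox(self._cohort(n=800))
        assert res.p_value < 0.05
        assert res.ci_low <= res.hr <= res.ci_high

    def test_constant_adjuster_dropped_estimate_unchanged(self):
        df = self._cohort().assign(surgery=1)
        full = interaction_cox(df)
        manual = interaction_cox(df, adjust=("age", "sex", "smoking_status"))
        assert full.hr == pytest.approx(manual.hr, rel=1e-9)

    def test_empty_cell_rejected(self):
        df = self._cohort()
        df = df[~((df["group"] == "benefit") & (df["tki_treated"] == 0))]
        with pytest.raises(ValueError, match="empty cell"):
            interaction_cox(df)


class TestBreslowLoglik:
    def test_matches_direct_enumeration_without_ties(self, rng):
        n = 12
        lp = rng.normal(size=n)
        time = rng.exponential(size=n) + np.arange(n) * 1e-3
        event = rng.integers(0, 2, size=n)
        order = np.argsort(time)
        ll = 0.0
        for i in order:
            if event[i]:
                risk = np.exp(lp[time >= time[i]]).sum()
                ll += lp[i] - np.log(risk)
        assert cox_breslow_loglik(lp, time, event) == pytest.approx(ll)
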