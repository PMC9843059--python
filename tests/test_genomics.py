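import numpy as np
import pandas as pd
import pytest

from tmepipe.genomics import (
    MARKER_PANELS,
    bh_adjust,
    enrichment_score,
    filter_genes,
    marker_panel_summary,
    preranked_gsea,
    rank_genes,
    shuffle_control,
)
from tmepipe.io import GeneSetCollection


def running_sum_oracle(rho_sorted, member_mask, exponent=1.0):
    """Direct evaluation of the weighted KS running sum at every position."""
    N = len(rho_sorted)
    m = member_mask.sum()
    w = np.abs(rho_sorted) ** exponent
    total = w[member_mask].sum()
    s, best = 0.0, 0.0
    trace = []
    for i in range(N):
        if member_mask[i]:
            s += w[i] / total
        else:
            s -= 1.0 / (N - m)
        trace.append(s)
        if abs(s) > abs(best):
            best = s
    return best, np.array(trace)


def expr_frame(values, patients=None):
    values = np.atleast_2d(values)
    patients = patients or [f"P{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"G{i}" for i in range(len(values))], columns=patients)


class TestFilterGenes:
    def test_boundary_at_twenty_percent(self):
        # 10 patients: 2 zeros = 20% retained, 3 zeros = 30% removed
        keep = [0.0, 0.0] + [1.0] * 8
        drop = [0.0, 0.0, 0.0] + [1.0] * 7
        expr = expr_frame([keep, drop])
        out = filter_genes(expr)
        assert list(out.index) == ["G0"]

    def test_all_zero_gene_removed(self):
        expr = expr_frame([[0.0] * 5, [1.0] * 5])
        assert list(filter_genes(expr).index) == ["G1"]

    def test_zero_fraction_enumeration(self):
        # zero fractions 0.0 .. 0.9: exactly three survive the 0.20 cutoff
        rows = []
        for k in range(10):
            rows.append([0.0] * k + [1.0] * (10 - k))
        out = filter_genes(expr_frame(rows))
        assert list(out.index) == ["G0", "G1", "G2"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_genes(pd.DataFrame())


class TestRankGenes:
    def test_monotone_transform_gives_rho_one(self):
        f = pd.Series([0.1, 0.4, 0.2, 0.9, 0.5], index=[f"P{i}" for i in range(5)])
        expr = expr_frame([np.exp(f.to_numpy())])
        r = rank_genes(expr, f)
        assert r.table.loc["G0", "rho"] == pytest.approx(1.0)

    def test_hand_computed_five_point_permutation(self):
        # ranks y = (3,1,2,4,5): sum d^2 = 6 -> rho = 1 - 36/120 = 0.7
        f = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=[f"P{i}" for i in range(5)])
        expr = expr_frame([[3.0, 1.0, 2.0, 4.0, 5.0], [2.0, 1.0, 4.0, 3.0, 5.0]])
        r = rank_genes(expr, f)
        assert r.table.loc["G0", "rho"] == pytest.approx(0.7)
        # ranks (2,1,4,3,5): sum d^2 = 4 -> rho = 0.8
        assert r.table.loc["G1", "rho"] == pytest.approx(0.8)

    def test_constant_gene_excluded(self):
        f = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"P{i}" for i in range(4)])
        expr = expr_frame([[5.0] * 4, [1.0, 2.0, 3.0, 4.0]])
        r = rank_genes(expr, f)
        assert "G0" not in r.table.index
        assert r.excluded_constant == ("G0",)

    def test_too_few_common_patients_rejected(self):
        f = pd.Series([1.0, 2.0], index=["P0", "P1"])
        with pytest.raises(ValueError, match="common patients"):
            rank_genes(expr_frame([[1.0, 2.0]]), f)

    def test_table_sorted_by_rho_descending(self, rng):
        f = pd.Series(rng.normal(size=20), index=[f"P{i}" for i in range(20)])
        expr = expr_frame(rng.uniform(0, 5, size=(15, 20)))
        r = rank_genes(expr, f)
        assert (np.diff(r.rho) <= 1e-12).all()

    def test_agrees_with_scipy_spearman(self, rng):
        from scipy import stats

        f = pd.Series(rng.normal(size=25), index=[f"P{i}" for i in range(25)])
        expr = expr_frame(rng.uniform(0, 5, size=(8, 25)))
        r = rank_genes(expr, f)
        for g in expr.index:
            rho, p = stats.spearmanr(expr.loc[g], f)
            assert r.table.loc[g, "rho"] == pytest.approx(rho)
            assert r.table.loc[g, "p"] == pytest.approx(p, rel=1e-6)


class TestEnrichmentScore:
    def test_top_block_set_peaks_at_block_end(self, rng):
        rho = np.sort(rng.uniform(-1, 1, size=50))[::-1]
        mask = np.zeros(50, dtype=bool)
        mask[:10] = True
        es, i_ext = enrichment_score(rho, mask)
        assert es > 0 and i_ext == 9

    def test_matches_running_sum_oracle_20_genes(self, rng):
        rho = np.sort(rng.uniform(-1, 1, size=20))[::-1]
        mask = np.zeros(20, dtype=bool)
        mask[[2, 7, 11, 16]] = True
        es, _ = enrichment_score(rho, mask)
        oracle_es, trace = running_sum_oracle(rho, mask)
        assert es == pytest.approx(oracle_es, abs=1e-12)
        assert abs(es) <= 1.0 + 1e-12
        assert np.max(np.abs(trace)) == pytest.approx(abs(es), abs=1e-12)

    def test_improper_set_rejected(self, rng):
        rho = np.sort(rng.uniform(-1, 1, size=10))[::-1]
        with pytest.raises(ValueError):
            enrichment_score(rho, np.zeros(10, dtype=bool))
        with pytest.raises(ValueError):
            enrichment_score(rho, np.ones(10, dtype=bool))

    def test_reversed_ranking_flips_sign_exponent_zero(self, rng):
        for _ in range(5):
            rho = np.sort(rng.uniform(-1, 1, size=40))[::-1]
            mask = np.zeros(40, dtype=bool)
            mask[rng.choice(40, size=8, replace=False)] = True
            es, _ = enrichment_score(rho, mask, exponent=0.0)
            es_rev, _ = enrichment_score(rho[::-1], mask[::-1], exponent=0.0)
            assert es_rev == pytest.approx(-es, abs=1e-12)


class TestPrerankedGsea:
    def _ranking(self, rng, n=100):
        from tmepipe.genomics import GeneRanking

        rho = np.sort(rng.uniform(-0.9, 0.9, size=n))[::-1]
        tab = pd.DataFrame(
            {"rho": rho, "p": 0.5}, index=[f"G{i:03d}" for i in range(n)]
        )
        return GeneRanking(feature="f", table=tab, n_patients=50)

    def test_top_set_enriched_and_deterministic(self, rng):
        ranking = self._ranking(rng)
        sets = GeneSetCollection({"TOP": tuple(ranking.genes[:10]), "RAND": tuple(ranking.genes[40:50])})
        a = preranked_gsea(ranking, sets, n_permutations=500, seed=1)
        b = preranked_gsea(ranking, sets, n_permutations=500, seed=1)
        assert a.loc["TOP", "es"] > 0
        assert a.loc["TOP", "p"] < a.loc["RAND", "p"]
        pd.testing.assert_frame_equal(a, b)

    def test_p_values_respect_smoothing_floor(self, rng):
        ranking = self._ranking(rng)
        sets = GeneSetCollection({"TOP": tuple(ranking.genes[:10])})
        res = preranked_gsea(ranking, sets, n_permutations=200, seed=2)
        assert res["p"].between(1 / 201, 1).all()
        assert (res["p_adjusted"] >= res["p"] - 1e-15).all()

    def test_size_filter_empty_result(self, rng):
        ranking = self._ranking(rng)
        sets = GeneSetCollection({"TINY": tuple(ranking.genes[:2])})
        res = preranked_gsea(ranking, sets, min_size=5, seed=0)
        assert res.empty

    def test_leading_edge_within_set(self, rng):
        ranking = self._ranking(rng)
        members = tuple(ranking.genes[[1, 5, 9, 13, 17, 30]])
        res = preranked_gsea(ranking, sets=GeneSetCollection({"S": members}), n_permutations=200, seed=0)
        assert set(res.loc["S", "leading_edge"]) <= set(members)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_order_preserving(self, rng):
        p = np.sort(rng.uniform(size=15))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()
        # constant adjusted blocks are fixed points of re-adjustment
        np.testing.assert_allclose(bh_adjust([0.04] * 4), [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestShuffleControl:
    def test_same_seed_same_result(self, rng):
        from tmepipe.simulate import ExpressionSimParams, simulate_expression, simulate_features

        f = simulate_features(30, seed=1)["interaction_tumor_stroma"]
        expr, sets = simulate_expression(f, ExpressionSimParams(n_genes=100, n_correlated=20), seed=2)
        a = shuffle_control(expr, f, sets, seed=3, n_permutations=200)
        b = shuffle_control(expr, f, sets, seed=3, n_permutations=200)
        pd.testing.assert_frame_equal(a, b)


class TestMarkerPanels:
    def test_builtin_panels_nonempty_upper(self):
        for name, genes in MARKER_PANELS.items():
            assert genes and all(g == g.upper() for g in genes)

    def test_monotone_gene_gives_monotone_bins(self, rng):
        n = 50
        pats = [f"P{i}" for i in range(n)]
        f = pd.Series(np.linspace(0, 1, n), index=pats)
        vim = f.to_numpy() * 3 + rng.normal(0, 0.01, n)
        expr = pd.DataFrame([vim], index=["VIM"], columns=pats)
        out = marker_panel_summary(expr, f, panels={"mes": ("VIM",)}, n_bins=5)
        bins = out.loc[0, [f"bin_{b}" for b in range(5)]].to_numpy(float)
        assert (np.diff(bins) > 0).all()
        assert out.loc[0, "rho"] > 0.95

    def test_bin_means_match_groupby_oracle(self, rng):
        n = 40
        pats = [f"P{i}" for i in range(n)]
        f = pd.Series(rng.normal(size=n), index=pats)
        g = rng.uniform(0, 5, size=n)
        expr = pd.DataFrame([g], index=["ACTA2"], columns=pats)
        out = marker_panel_summary(expr, f, panels={"p": ("ACTA2",)}, n_bins=4)
        z = (g - g.mean()) / g.std(ddof=0)
        bins = pd.qcut(f.rank(method="first"), q=4, labels=False)
        for b in range(4):
            assert out.loc[0, f"bin_{b}"] == pytest.approx(z[bins.to_numpy() == b].mean())

    def test_missing_gene_not_fatal(self, rng):
        n = 20
        pats = [f"P{i}" for i in range(n)]
        f = pd.Series(rng.normal(size=n), index=pats)
        expr = pd.DataFrame([rng.uniform(size=n)], index=["VIM"], columns=pats)
        out = marker_panel_summary(expr, f, panels={"mes": ("VIM", "ZEB1")}, n_bins=4)
        assert list(out["gene"]) == ["VIM"]

    def test_too_many_bins_rejected(self, rng):
        pats = [f"P{i}" for i in range(3)]
        f = pd.Series([1.0, 2.0, 3.0], index=pats)
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["VIM"], columns=pats)
        with pytest.raises(ValueError):
            marker_panel_summary(expr, f, panels={"m": ("VIM",)}, n_bins=5)
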