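"""Validation statistics against brute-force and hand-computed oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trmtime as tm
from trmtime.validate import default_growth_sets


def _sig(name, genes):
    return tm.GeneSignature(name, tuple(genes), {"source": "test"})


def _frame(array, genes=None, cols=None):
    array = np.asarray(array, dtype=float)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    cols = cols or [f"c{i}" for i in range(array.shape[1])]
    return pd.DataFrame(array, index=genes, columns=cols)


class TestScoreSignature:
    def test_single_gene_score_is_its_z_row(self):
        values = _frame([[1.0, 2.0, 3.0], [5.0, 5.0, 6.0]])
        score = tm.score_signature(values, _sig("s", ["g0"]))
        row = values.loc["g0"]
        z = (row - row.mean()) / row.std(ddof=1)
        np.testing.assert_allclose(score.to_numpy(), z.to_numpy())

    def test_identical_columns_score_zero(self):
        values = _frame([[2.0, 2.0, 2.0], [1.0, 1.0, 1.0]])
        score = tm.score_signature(values, _sig("s", ["g0", "g1"]))
        np.testing.assert_allclose(score.to_numpy(), 0.0)

    def test_hand_3x3(self):
        values = _frame([[1.0, 2.0, 3.0], [0.0, 4.0, 2.0], [9.0, 9.0, 9.0]])
        score = tm.score_signature(values, _sig("s", ["g0", "g1", "g2"]))
        z0 = (np.array([1, 2, 3]) - 2.0) / 1.0
        z1 = (np.array([0, 4, 2]) - 2.0) / 2.0
        np.testing.assert_allclose(score.to_numpy(), (z0 + z1) / 2)  # g2 flat, skipped

    def test_absent_genes_error(self):
        values = _frame([[1.0, 2.0]])
        with pytest.raises(tm.ValidationError):
            tm.score_signature(values, _sig("s", ["missing"]))

    def test_gene_order_invariant(self):
        rng = np.random.default_rng(0)
        values = _frame(rng.normal(size=(6, 5)))
        a = tm.score_signature(values, _sig("s", ["g0", "g3", "g5"]))
        b = tm.score_signature(values, _sig("s", ["g5", "g0", "g3"]))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


class TestSegregation:
    def test_two_blocks_perfectly_segregate(self):
        rng = np.random.default_rng(0)
        resident = np.array([3.0, 2.0, 4.0, 1.0])[:, None] + 0.05 * rng.normal(size=(4, 5))
        circulating = np.array([0.0, 1.0, -1.0, 2.0])[:, None] + 0.05 * rng.normal(size=(4, 5))
        values = _frame(np.hstack([resident, circulating]))
        labels = ["resident"] * 5 + ["other"] * 5
        res = tm.hierarchical_segregation(values, _sig("s", list(values.index)), labels)
        assert res.purity == 1.0

    def test_null_purity_band(self):
        """Random labels on structureless noise give intermediate purity."""
        purities = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = _frame(rng.normal(size=(20, 12)))
            labels = ["resident"] * 6 + ["other"] * 6
            res = tm.hierarchical_segregation(values, _sig("s", list(values.index)), labels)
            purities.append(res.purity)
        assert all(0.5 <= p <= 1.0 for p in purities)
        assert 0.5 <= float(np.mean(purities)) <= 0.75

    def test_hand_agglomeration_order(self):
        """Two tight pairs merge first; the cross-pair merge comes last."""
        base = np.array([[1.0, -1.0, 0.5], [-1.0, 1.0, -0.5]])
        cols = {
            "a1": base[0], "a2": base[0] * 1.1 + 0.01,
            "b1": base[1], "b2": base[1] * 0.9 - 0.02,
        }
        values = _frame(np.column_stack(list(cols.values())), genes=["g0", "g1", "g2"],
                        cols=list(cols))
        res = tm.hierarchical_segregation(
            values, _sig("s", ["g0", "g1", "g2"]), ["r", "r", "o", "o"]
        )
        first_two = {tuple(sorted(res.linkage[i, :2].astype(int))) for i in range(2)}
        assert first_two == {(0, 1), (2, 3)}  # (a1,a2) then (b1,b2)
        assert res.purity == 1.0

    def test_input_validation(self):
        values = _frame(np.ones((3, 3)))
        with pytest.raises(tm.ValidationError):
            tm.hierarchical_segregation(values, _sig("s", ["g0", "g1"]), ["a", "a", "b"])


class TestRankTwoGroups:
    def test_extreme_gene_tops_ranking(self):
        rng = np.random.default_rng(0)
        values = _frame(rng.normal(size=(20, 8)))
        values.iloc[0, :4] += 10.0
        labels = ["a"] * 4 + ["b"] * 4
        ranked = tm.rank_two_groups(values, labels, "a", "b")
        assert ranked["gene"].iloc[0] == "g0"
        assert ranked["stat"].iloc[0] > 0

    def test_identical_groups_rank_zero(self):
        block = np.tile(np.arange(4.0), (5, 1))
        values = _frame(np.hstack([block, block]))
        labels = ["a"] * 4 + ["b"] * 4
        ranked = tm.rank_two_groups(values, labels, "a", "b")
        np.testing.assert_allclose(ranked["stat"].to_numpy(), 0.0)

    def test_matches_rank_sum_oracle(self):
        """Signed statistic agrees with an exhaustive rank-sum computation."""
        a = np.array([5.0, 7.0, 9.0])
        b = np.array([1.0, 2.0, 8.0])
        values = _frame(np.r_[a, b][None, :])
        ranked = tm.rank_two_groups(values, ["a"] * 3 + ["b"] * 3, "a", "b")
        u = sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in a for y in b
        )
        n1 = n2 = 3
        mu, sd = n1 * n2 / 2, math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        z = (u - mu - 0.5) / sd  # continuity-corrected normal approximation
        p = 2 * (1 - 0.5 * (1 + math.erf(abs(z) / math.sqrt(2))))
        assert ranked["stat"].iloc[0] == pytest.approx(-math.log10(p), rel=1e-6)


class TestGsea:
    def _ranking(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        stats = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(stats, index=[f"g{i}" for i in range(n)])

    def test_top_set_enriched(self):
        ranking = self._ranking()
        res = tm.preranked_gsea(
            ranking, _sig("top", [f"g{i}" for i in range(5)]), n_perm=1000, seed=0
        )
        assert res.es > 0
        assert res.p_value <= 0.01
        assert set(res.leading_edge) <= {f"g{i}" for i in range(5)}

    def test_bottom_set_negative(self):
        ranking = self._ranking()
        res = tm.preranked_gsea(
            ranking, _sig("bottom", [f"g{i}" for i in range(95, 100)]),
            n_perm=1000, seed=0,
        )
        assert res.es < 0
        assert np.sign(res.nes) == np.sign(res.es)

    def test_weight_zero_top_set_es_is_one(self):
        ranking = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.2, 0.1],
                            index=[f"g{i}" for i in range(8)])
        res = tm.preranked_gsea(
            ranking, _sig("top", ["g0", "g1"]), n_perm=100, weight_exponent=0.0,
            seed=0, method="exhaustive",
        )
        assert res.es == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration(self):
        """Empirical p over all C(5,2)=10 assignments equals the enumerated one."""
        stats = pd.Series([3.0, 2.0, 1.5, 1.0, 0.5],
                          index=["g0", "g1", "g2", "g3", "g4"])
        res = tm.preranked_gsea(
            stats, _sig("set", ["g0", "g3"]), n_perm=100, weight_exponent=0.0,
            seed=1, method="exhaustive",
        )

        def oracle_es(positions):
            running, best = 0.0, 0.0
            for i in range(5):
                running += 0.5 if i in positions else -1.0 / 3.0
                if abs(running) > abs(best):
                    best = running
            return best

        observed = oracle_es({0, 3})
        null = [oracle_es(set(c)) for c in itertools.combinations(range(5), 2)]
        p_oracle = sum(abs(e) >= abs(observed) - 1e-12 for e in null) / len(null)
        assert res.es == pytest.approx(observed)
        assert res.p_value == pytest.approx(p_oracle)
        assert res.n_permutations == 10

    def test_es_bounds_and_p_floor(self):
        ranking = self._ranking(n=40, seed=3)
        res = tm.preranked_gsea(
            ranking, _sig("s", [f"g{i}" for i in range(0, 40, 7)]), n_perm=200, seed=2
        )
        assert -1.0 <= res.es <= 1.0
        assert res.p_value >= 1.0 / (res.n_permutations + 1)

    def test_no_overlap_and_degenerate_errors(self):
        ranking = self._ranking(n=10)
        with pytest.raises(tm.ValidationError):
            tm.preranked_gsea(ranking, _sig("s", ["absent"]), n_perm=100)
        zeros = pd.Series(np.zeros(10), index=[f"g{i}" for i in range(10)])
        with pytest.raises(tm.ValidationError):
            tm.preranked_gsea(zeros, _sig("s", ["g0", "g1"]), n_perm=100)


class TestAucMarkers:
    def test_perfect_and_null_separation(self):
        values = _frame([[1, 2, 3, 10, 11, 12], [5, 5, 5, 5, 5, 5]])
        clusters = ["a", "a", "a", "b", "b", "b"]
        res = tm.auc_markers(values, clusters, auc_min=0.75)
        b_rows = res[res["cluster"] == "b"].set_index("gene")
        assert b_rows.loc["g0", "auc"] == 1.0
        assert b_rows.loc["g1", "auc"] == 0.5  # all tied -> midranks give 0.5
        assert bool(b_rows.loc["g0", "marker"])

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_all_pairs_oracle(self, seed):
        """AUC equals the brute-force pairwise comparison proportion."""
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=12), 1)  # rounding forces ties
        clusters = np.array(["a"] * 5 + ["b"] * 7)
        values = _frame(x[None, :])
        res = tm.auc_markers(values, clusters, auc_min=0.75).set_index("cluster")
        in_a, in_b = x[:5], x[5:]
        oracle = np.mean(
            [1.0 if xi > xj else 0.5 if xi == xj else 0.0 for xi in in_a for xj in in_b]
        )
        assert res.loc["a", "auc"] == pytest.approx(oracle, abs=1e-12)
        assert res.loc["b", "auc"] == pytest.approx(1 - oracle, abs=1e-12)

    def test_singleton_cluster_skipped(self):
        values = _frame(np.arange(5.0)[None, :])
        res = tm.auc_markers(values, ["a", "a", "b", "b", "c"])
        assert set(res["cluster"]) == {"a", "b"}


class TestOvaPseudobulkDe:
    def _dataset(self, factor=2.0, n=24, seed=0):
        import scipy.sparse as sp

        rng = np.random.default_rng(seed)
        base = rng.poisson(50, size=(20, n)).astype(float)
        genes = [f"g{i}" for i in range(20)]
        clusters = np.array(["hot"] * (n // 2) + ["cold"] * (n // 2))
        base[0, clusters == "hot"] *= factor
        counts = tm.CountMatrix(genes, [f"c{i}" for i in range(n)],
                                sp.csr_matrix(base.astype(int)))
        meta = pd.DataFrame({"barcode": counts.barcodes, "tissue": "skin",
                             "day": 0.0, "cluster": clusters})
        return counts, meta

    def test_doubled_gene_log2fc_near_one(self):
        counts, meta = self._dataset(factor=2.0)
        res = tm.ova_pseudobulk_de(counts, meta, n_replicates=3, seed=0)
        hot = res[(res["cluster"] == "hot") & (res["gene"] == "g0")].iloc[0]
        assert hot["log2fc"] == pytest.approx(1.0, abs=0.2)
        assert hot["q"] < 0.05

    def test_no_difference_log2fc_near_zero(self):
        counts, meta = self._dataset(factor=1.0, n=60)
        res = tm.ova_pseudobulk_de(counts, meta, n_replicates=3, seed=0)
        assert res["log2fc"].abs().max() < 0.2

    def test_t_statistic_matches_closed_form(self):
        """p for a 2-replicate-per-side design matches the hand t-test."""
        counts, meta = self._dataset(factor=3.0, n=16, seed=1)
        meta["replicate"] = np.tile([0, 1], 8)
        res = tm.ova_pseudobulk_de(counts, meta, replicate_col="replicate")
        # recompute the replicate LogCPM values exactly as documented
        import scipy.stats

        dense = counts.to_dense().astype(float)
        rows = {}
        for side_mask, side in [((meta["cluster"] == "hot").to_numpy(), "hot")]:
            cols = []
            for r in (0, 1):
                sel = side_mask & (meta["replicate"] == r).to_numpy()
                s = dense[:, sel].sum(axis=1)
                cols.append(np.log2(1e6 * s / s.sum() + 1.0))
            rows[side] = np.column_stack(cols)
        rest = []
        for r in (0, 1):
            sel = (~(meta["cluster"] == "hot").to_numpy()) & (meta["replicate"] == r).to_numpy()
            s = dense[:, sel].sum(axis=1)
            rest.append(np.log2(1e6 * s / s.sum() + 1.0))
        p_oracle = scipy.stats.ttest_ind(rows["hot"], np.column_stack(rest), axis=1).pvalue
        got = res[res["cluster"] == "hot"].set_index("gene")
        np.testing.assert_allclose(
            got.loc[[f"g{i}" for i in range(20)], "p"].to_numpy(),
            np.nan_to_num(p_oracle, nan=1.0),
            atol=1e-10,
        )

    def test_insufficient_replicates_error(self):
        counts, meta = self._dataset(n=8)
        meta["replicate"] = 0
        with pytest.raises(tm.ValidationError, match="replicate"):
            tm.ova_pseudobulk_de(counts, meta, replicate_col="replicate")


class TestProfileCorrelation:
    def test_self_and_flip(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=12)
        table = pd.DataFrame({"c1": prof, "c2": -prof, "c3": prof + 0.01 * rng.normal(size=12)},
                             index=[f"g{i}" for i in range(12)])
        corr = tm.cluster_profile_correlation(table)
        assert corr.loc["c1", "c1"] == 1.0
        assert corr.loc["c1", "c2"] == pytest.approx(-1.0)
        assert corr.loc["c1", "c3"] > 0.9

    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"],
                             index=[f"g{i}" for i in range(12)])
        corr = tm.cluster_profile_correlation(table)
        ra = table["a"].rank().to_numpy()
        rb = table["b"].rank().to_numpy()
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert corr.loc["a", "b"] == pytest.approx(oracle, abs=1e-12)

    def test_small_universe_rejected(self):
        table = pd.DataFrame(np.ones((5, 2)), columns=["a", "b"])
        with pytest.raises(tm.ValidationError):
            tm.cluster_profile_correlation(table)


class TestGrowthScore:
    def test_antisymmetry_and_signs(self):
        rng = np.random.default_rng(0)
        values = _frame(rng.normal(size=(8, 6)))
        prolif = _sig("proliferation", ["g0", "g1", "g2"])
        apop = _sig("apoptosis", ["g5", "g6", "g7"])
        fwd = tm.growth_score(values, prolif, apop)
        rev = tm.growth_score(values, apop, prolif)
        np.testing.assert_allclose(
            fwd["log_growth_rate"].to_numpy(), -rev["log_growth_rate"].to_numpy()
        )

    def test_high_proliferation_cell_scores_positive(self):
        values = _frame(np.zeros((4, 3)))
        values.iloc[:2, 0] = 5.0  # cell c0 high in proliferation genes
        values.iloc[2:, 1] = 5.0  # cell c1 high in apoptosis genes
        fwd = tm.growth_score(values, _sig("p", ["g0", "g1"]), _sig("a", ["g2", "g3"]))
        assert fwd.loc["c0", "log_growth_rate"] > 0
        assert fwd.loc["c1", "log_growth_rate"] < 0

    def test_bundled_sets_load(self):
        prolif, apop = default_growth_sets()
        assert "Mki67" in prolif.genes
        assert "Bax" in apop.genes
        assert not (set(prolif.genes) & set(apop.genes))
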