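import itertools

import numpy as np
import pandas as pd
import pytest

from lobeomics.diff import ComparisonResult
from lobeomics.enrichment import (
    RankedList,
    gated_t_matrix,
    gsea_es,
    gsea_nes,
    qc_filter,
    rank_genes,
    ranksum_markers,
    sample_set_score,
    score_matrix,
    signature_score,
    stratify,
)


def es_bruteforce(gene_ids, scores, members, weight=1.0):
    """Independent running-sum oracle (plain loop, no vectorization)."""
    n = len(gene_ids)
    hits = [g in members for g in gene_ids]
    n_hits = sum(hits)
    denom_hit = sum(abs(s) ** weight for g, s in zip(gene_ids, scores) if g in members)
    running, best = 0.0, 0.0
    for g, s, h in zip(gene_ids, scores, hits):
        if h:
            if denom_hit > 0:
                running += abs(s) ** weight / denom_hit
            else:
                running += 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


def _result(g_by_gene):
    genes = sorted(g_by_gene)
    g = np.array([g_by_gene[x] for x in genes], dtype=float)
    tab = pd.DataFrame(
        {"log2fc": g, "se": 1.0, "p": 0.01, "padj": 0.01, "g": g},
        index=pd.Index(genes, name="gene_id"),
    )
    return ComparisonResult(tab, "MvG", "L")


class TestRankGenes:
    def test_orders_by_g_descending_excluding_zeros(self):
        ranked = rank_genes(_result({"a": 2.0, "b": -1.0, "c": 0.0}))
        assert ranked.gene_ids == ["a", "b"]

    def test_ties_break_lexicographically(self):
        ranked = rank_genes(_result({"b": 1.0, "a": 1.0}))
        assert ranked.gene_ids == ["a", "b"]

    def test_too_few_nonzero_errors(self):
        with pytest.raises(ValueError, match="nonzero"):
            rank_genes(_result({"a": 1.0, "b": 0.0}))


class TestGseaEs:
    def test_top_gene_equal_weights_is_one(self):
        ranked = RankedList(["a", "b", "c", "d"], np.array([1.0, 1.0, 1.0, 1.0]))
        assert gsea_es(ranked, {"a"}) == pytest.approx(1.0)

    def test_bottom_gene_equal_weights_is_minus_one(self):
        ranked = RankedList(["a", "b", "c", "d"], np.array([1.0, 1.0, 1.0, 1.0]))
        assert gsea_es(ranked, {"d"}) == pytest.approx(-1.0)

    def test_degenerate_sets_rejected(self):
        ranked = RankedList(["a", "b"], np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            gsea_es(ranked, {"x"})
        with pytest.raises(ValueError):
            gsea_es(ranked, {"a", "b"})

    def test_matches_bruteforce_oracle_on_random_lists(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = int(rng.integers(3, 21))
            genes = [f"g{i}" for i in range(n)]
            scores = np.sort(rng.normal(size=n) * 2)[::-1]
            ranked = RankedList(genes, scores)
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False))
            expected = es_bruteforce(genes, scores, members)
            assert gsea_es(ranked, members) == pytest.approx(expected)


class TestGseaNes:
    def _ranked(self, n=60, seed=11):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return RankedList([f"g{i}" for i in range(n)], scores)

    def test_mean_abs_nes_near_one_for_random_sets(self):
        rng = np.random.default_rng(12)
        ranked = self._ranked()
        sets = {
            f"s{k}": list(rng.choice(ranked.gene_ids, size=8, replace=False))
            for k in range(50)
        }
        tab = gsea_nes(ranked, sets, n_perm=200, seed=0)
        assert 0.8 <= tab["nes"].abs().mean() <= 1.2
        assert (np.sign(tab["nes"]) == np.sign(tab["es"])).all()
        assert (tab["p"] >= 1 / 201).all()

    def test_planted_top_set_significant_positive(self):
        ranked = self._ranked()
        top = ranked.gene_ids[:8]
        rng = np.random.default_rng(13)
        sets = {"top": top}
        sets.update(
            {f"r{k}": list(rng.choice(ranked.gene_ids, size=8, replace=False))
             for k in range(10)}
        )
        tab = gsea_nes(ranked, sets, n_perm=1000, seed=1).set_index("set_name")
        assert tab.loc["top", "nes"] > 0
        assert tab.loc["top", "padj"] <= 0.05

    def test_seed_reproducibility(self):
        ranked = self._ranked()
        sets = {"s": ranked.gene_ids[5:12]}
        a = gsea_nes(ranked, sets, n_perm=200, seed=7)
        b = gsea_nes(ranked, sets, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_low_n_perm_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            gsea_nes(self._ranked(), {"s": ["g1"]}, n_perm=10)


class TestSampleSetScore:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(14)
        expr = pd.Series(rng.random(30), index=[f"g{i}" for i in range(30)])
        members = {"g1", "g5", "g20"}
        s1 = sample_set_score(expr, members)
        s2 = sample_set_score(np.exp(3 * expr), members)
        assert s1 == pytest.approx(s2)

    def test_top_placement_is_maximal_exhaustively(self):
        genes = [f"g{i}" for i in range(8)]
        values = np.array([8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        scores = {}
        for pair in itertools.combinations(genes, 2):
            scores[pair] = sample_set_score(
                pd.Series(values, index=genes), set(pair)
            )
        top = ("g0", "g1")
        assert max(scores, key=scores.get) == top

    def test_identical_rank_order_identical_scores(self):
        genes = [f"g{i}" for i in range(10)]
        a = pd.Series(np.arange(10, 0, -1, dtype=float), index=genes)
        b = pd.Series(np.arange(10, 0, -1, dtype=float) * 7 + 3, index=genes)
        members = {"g2", "g4"}
        assert sample_set_score(a, members) == pytest.approx(
            sample_set_score(b, members)
        )

    def test_score_matrix_agrees_with_single_sample(self):
        rng = np.random.default_rng(15)
        mat = pd.DataFrame(
            rng.integers(0, 50, size=(5, 12)),
            index=[f"c{i}" for i in range(5)],
            columns=[f"g{i}" for i in range(12)],
        ).astype(float)
        members = {"g3", "g7", "g11"}
        tab = score_matrix(mat, {"s": sorted(members)})
        for cell in mat.index:
            assert tab.loc[cell, "s"] == pytest.approx(
                sample_set_score(mat.loc[cell], members)
            )

    def test_full_coverage_rejected(self):
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            sample_set_score(expr, {"a", "b"})


class TestQcFilter:
    def _metrics(self, **kw):
        row = {"nFeature": 1000, "nCount": 5000, "pct_mito": 5.0, "pct_ribo": 10.0}
        row.update(kw)
        return pd.DataFrame([row], index=["c1"])

    @pytest.mark.parametrize(
        "kw",
        [
            {"nFeature": 300},
            {"nFeature": 7500},
            {"nCount": 400},
            {"nCount": 90000},
            {"pct_mito": 16.0},
            {"pct_ribo": 41.0},
        ],
    )
    def test_violations_flagged(self, kw):
        assert qc_filter(self._metrics(**kw)).iloc[0]

    def test_clean_cell_kept(self):
        assert not qc_filter(self._metrics()).iloc[0]

    def test_boundary_values_kept(self):
        # bounds are strict inequalities: exactly 400 / 15% etc. pass
        ok = self._metrics(nFeature=400, nCount=500, pct_mito=15.0, pct_ribo=40.0)
        assert not qc_filter(ok).iloc[0]

    def test_missing_metric_errors(self):
        with pytest.raises(ValueError, match="pct_ribo"):
            qc_filter(self._metrics().drop(columns=["pct_ribo"]))


class TestStratify:
    def test_median_split(self):
        labels = stratify(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_at_threshold_go_low(self):
        labels = stratify(pd.Series([1.0, 2.0, 2.0, 3.0]))
        assert list(labels) == ["low", "low", "low", "high"]

    def test_constant_scores_error(self):
        with pytest.raises(ValueError, match="constant"):
            stratify(pd.Series([2.0, 2.0, 2.0, 2.0]))

    def test_too_few_cells_error(self):
        with pytest.raises(ValueError, match="4 cells"):
            stratify(pd.Series([1.0, 2.0]))

    def test_planted_strata_recovered(self):
        from lobeomics.simulate import sim_sc

        matrix, truth = sim_sc(n_cells=600, seed=16)
        scores = signature_score(matrix, truth.signature_genes)
        labels = stratify(scores)
        agreement = (labels == truth.cells["stratum"]).mean()
        assert agreement >= 0.9


class TestRanksumMarkers:
    def _matrix(self, x, y):
        x, y = np.atleast_2d(x), np.atleast_2d(y)
        cells = [f"a{i}" for i in range(x.shape[0])] + [f"b{i}" for i in range(y.shape[0])]
        mat = pd.DataFrame(np.vstack([x, y]), index=cells,
                           columns=[f"g{i}" for i in range(x.shape[1])])
        groups = pd.Series(["A"] * x.shape[0] + ["B"] * y.shape[0], index=cells)
        return mat, groups

    def test_low_detection_excluded(self):
        # gene detected in 10% of both 10-cell groups: below min.pct
        x = np.zeros((10, 1)); x[0, 0] = 5
        y = np.zeros((10, 1)); y[0, 0] = 4
        mat, groups = self._matrix(x, y)
        assert len(ranksum_markers(mat, groups, min_pct=0.3)) == 0

    def test_identical_multisets_give_p_one(self):
        x = np.array([[1.0], [2.0], [3.0]])
        mat, groups = self._matrix(x, x.copy())
        res = ranksum_markers(mat, groups, min_pct=0.0)
        assert res["p"].iloc[0] == 1.0

    def test_exact_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            x = rng.integers(1, 30, size=(4, 1)).astype(float)
            y = rng.integers(1, 30, size=(5, 1)).astype(float)
            mat, groups = self._matrix(x, y)
            res = ranksum_markers(mat, groups, min_pct=0.0)
            # independent oracle: enumerate all group assignments of ranks
            from scipy.stats import rankdata

            pooled = np.concatenate([x[:, 0], y[:, 0]])
            ranks = rankdata(pooled)
            n1 = len(x)
            center = ranks.sum() * n1 / len(pooled)
            obs = abs(ranks[:n1].sum() - center)
            hits = total = 0
            for combo in itertools.combinations(range(len(pooled)), n1):
                total += 1
                if abs(ranks[list(combo)].sum() - center) >= obs - 1e-9:
                    hits += 1
            assert res["p"].iloc[0] == pytest.approx(hits / total)

    def test_small_groups_rejected(self):
        x = np.ones((2, 1)); y = np.ones((3, 1))
        mat, groups = self._matrix(x, y)
        with pytest.raises(ValueError, match="3 cells"):
            ranksum_markers(mat, groups)


class TestGatedTMatrix:
    def _scores(self, rng, n=40):
        cells = [f"c{i}" for i in range(2 * n)]
        scores = pd.DataFrame({"pw": rng.normal(size=2 * n)}, index=cells)
        strata = pd.Series(["high"] * n + ["low"] * n, index=cells)
        types = pd.Series(["T"] * 2 * n, index=cells)
        return scores, strata, types

    def test_insignificant_t_gated_to_zero(self):
        rng = np.random.default_rng(18)
        scores, strata, types = self._scores(rng)
        scores.loc[strata == "high", "pw"] += 0.1  # too small to survive BH
        tab = gated_t_matrix(scores, strata, types)
        row = tab.iloc[0]
        if row["padj"] > 0.05:
            assert row["gated_t"] == 0.0

    def test_identical_strata_zero(self):
        cells = [f"c{i}" for i in range(12)]
        scores = pd.DataFrame({"pw": np.tile([1.0, 2.0, 3.0], 4)}, index=cells)
        strata = pd.Series(["high", "low"] * 6, index=cells)
        types = pd.Series(["T"] * 12, index=cells)
        tab = gated_t_matrix(scores, strata, types)
        assert tab["gated_t"].iloc[0] == 0.0

    def test_strong_shift_reported_with_sign(self):
        rng = np.random.default_rng(19)
        scores, strata, types = self._scores(rng, n=100)
        scores.loc[strata == "high", "pw"] += 3.0
        tab = gated_t_matrix(scores, strata, types)
        assert tab["gated_t"].iloc[0] > 0
        assert tab["padj"].iloc[0] <= 0.05

    def test_small_stratum_flagged_not_computed(self):
        cells = [f"c{i}" for i in range(6)]
        scores = pd.DataFrame({"pw": np.arange(6.0)}, index=cells)
        strata = pd.Series(["high"] * 2 + ["low"] * 4, index=cells)
        types = pd.Series(["T"] * 6, index=cells)
        tab = gated_t_matrix(scores, strata, types)
        assert tab["flagged"].iloc[0]
        assert tab["gated_t"].iloc[0] == 0.0
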