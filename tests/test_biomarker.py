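"""Correlation ranking, preranked GSEA and group differential expression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vmtools import biomarker as bm
from vmtools.biomarker import RankedGeneList
from vmtools.synth import gen_expression


def _ranked(r_values, genes=None):
    genes = genes or [f"G{i}" for i in range(len(r_values))]
    order = np.argsort(-np.asarray(r_values), kind="stable")
    tab = pd.DataFrame({"r": np.asarray(r_values)[order],
                        "rank": np.arange(1, len(genes) + 1)},
                       index=np.asarray(genes)[order])
    return RankedGeneList(table=tab, n_lines=10)


class TestCorrelateSensitivity:
    def test_exact_linear_dependence_ranks_first(self):
        aac = pd.Series([0.1, 0.4, 0.5, 0.9], index=list("ABCD"))
        expr = pd.DataFrame({"A": [1.2, 5.0], "B": [1.8, 4.0],
                             "C": [2.0, 4.4], "D": [2.8, 3.1]},
                            index=["linear", "noisy"])
        expr.loc["linear"] = 2 * aac + 1
        ranked = bm.correlate_sensitivity(expr, aac)
        assert ranked.table.loc["linear", "r"] == pytest.approx(1.0)
        assert ranked.table.loc["linear", "rank"] == 1

    def test_constant_gene_gets_r_zero_and_last_rank(self):
        aac = pd.Series([0.1, 0.5, 0.9], index=list("ABC"))
        expr = pd.DataFrame({"A": [3.0, 1.0], "B": [3.0, 2.0],
                             "C": [3.0, 0.5]}, index=["flat", "other"])
        ranked = bm.correlate_sensitivity(expr, aac)
        assert ranked.table.loc["flat", "r"] == 0.0
        assert ranked.table.loc["flat", "rank"] == 2

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(0)
        aac = pd.Series(rng.uniform(0, 1, 8), index=[f"L{i}" for i in range(8)])
        expr = pd.DataFrame(rng.normal(size=(100, 8)), columns=aac.index,
                            index=[f"G{i}" for i in range(100)])
        ranked = bm.correlate_sensitivity(expr, aac)
        s = aac.to_numpy()
        for g in expr.index:
            x = expr.loc[g].to_numpy()
            r_oracle = (np.mean(x * s) - x.mean() * s.mean()) / \
                (x.std(ddof=0) * s.std(ddof=0))
            assert ranked.table.loc[g, "r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_affine_transform_of_sensitivity_preserves_r(self):
        rng = np.random.default_rng(1)
        aac = pd.Series(rng.uniform(0, 1, 6), index=[f"L{i}" for i in range(6)])
        expr = pd.DataFrame(rng.normal(size=(20, 6)), columns=aac.index)
        r1 = bm.correlate_sensitivity(expr, aac).table["r"]
        r2 = bm.correlate_sensitivity(expr, 0.25 * aac + 3.0).table["r"]
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_fewer_than_three_lines_rejected(self):
        aac = pd.Series([0.1, 0.9], index=list("AB"))
        expr = pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            bm.correlate_sensitivity(expr, aac)


class TestGseaPreranked:
    def test_single_top_hit_unweighted_running_sum(self):
        """Worked 3-gene case: hit at the top with p=0 climbs to +1 then
        descends by 1/2 per miss, so ES = 1.0 exactly."""
        ranked = _ranked([0.9, 0.1, -0.5])
        res = bm.gsea_preranked(ranked, {"top": [ranked.genes[0]]},
                                weight_p=0.0, n_perm=100, seed=0, min_size=1)
        assert res.table.loc["top", "es"] == pytest.approx(1.0)

    def test_whole_universe_set_skipped_with_warning(self):
        ranked = _ranked([0.9, 0.1, -0.5])
        with pytest.warns(UserWarning, match="universe"):
            res = bm.gsea_preranked(ranked, {"all": ranked.genes},
                                    n_perm=50, seed=0)
        assert "all" not in res.table.index

    def test_small_case_p_matches_exhaustive_enumeration(self):
        """N=6, |S|=2: the permutation p equals a brute-force enumeration
        over all 15 hit-position configurations."""
        r = np.array([0.9, 0.6, 0.3, -0.2, -0.5, -0.8])
        ranked = _ranked(r)
        genes = ranked.genes
        for members in [(0, 1), (0, 5), (2, 4)]:
            set_genes = [genes[i] for i in members]
            res = bm.gsea_preranked(ranked, {"S": set_genes}, weight_p=1.0,
                                    n_perm=1000, seed=3)
            es_obs = res.table.loc["S", "es"]
            # independent enumeration oracle
            w = np.abs(np.sort(r)[::-1])
            null = []
            for combo in itertools.combinations(range(6), 2):
                mask = np.zeros(6, dtype=bool)
                mask[list(combo)] = True
                steps = np.where(mask, w * mask / (w * mask).sum(), -1 / 4)
                run = np.cumsum(steps)
                null.append(run[np.argmax(np.abs(run))])
            null = np.array(null)
            same = null if es_obs >= 0 else -null
            same = same[same > 0]
            p_exact = np.sum(same >= abs(es_obs)) / same.size
            assert res.table.loc["S", "p_value"] == pytest.approx(
                p_exact, abs=2 / 1001)

    def test_es_bounded_and_nes_sign_matches(self):
        rng = np.random.default_rng(5)
        r = np.sort(rng.normal(size=40))[::-1]
        ranked = _ranked(r)
        sets = {f"S{i}": list(rng.choice(ranked.genes, 5, replace=False))
                for i in range(6)}
        res = bm.gsea_preranked(ranked, sets, n_perm=100, seed=0)
        assert (res.table["es"].abs() <= 1.0 + 1e-12).all()
        finite = res.table.dropna(subset=["nes"])
        assert (np.sign(finite["nes"]) == np.sign(finite["es"])).all()

    def test_null_ranking_p_values_are_valid(self):
        """Under a shuffled statistic, the fraction of sets with p < alpha
        stays within binomial slack of alpha."""
        rng = np.random.default_rng(11)
        r = rng.normal(size=120)
        ranked = _ranked(np.sort(r)[::-1])
        n_sets = 40
        sets = {f"S{i}": list(rng.choice(ranked.genes, 8, replace=False))
                for i in range(n_sets)}
        res = bm.gsea_preranked(ranked, sets, n_perm=200, seed=2)
        alpha = 0.1
        frac = float((res.table["p_value"] < alpha).mean())
        assert frac <= alpha + 3 * np.sqrt(alpha / n_sets)

    def test_planted_signature_beats_decoys(self):
        aac = pd.Series(np.linspace(0.05, 0.85, 17),
                        index=[f"L{i}" for i in range(17)])
        signature = [f"ISG{i:03d}" for i in range(50)]
        expr = gen_expression(21, 1000, aac, signature, strength=0.8)
        ranked = bm.correlate_sensitivity(expr, aac)
        rng = np.random.default_rng(22)
        sets = {"SIGNATURE": signature}
        for d in range(20):
            sets[f"DECOY_{d}"] = rng.choice(expr.index.to_numpy(), 50,
                                            replace=False).tolist()
        res = bm.gsea_preranked(ranked, sets, n_perm=200, seed=4)
        top = bm.top_pathways(res, k=1)
        assert top.index[0] == "SIGNATURE"


class TestGroupDifferential:
    def test_identical_groups_give_zero_fc_p_one(self):
        expr = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["g"],
                            columns=list("ABCD"))
        labels = pd.Series(["x", "x", "y", "y"], index=list("ABCD"))
        out = bm.group_differential(expr, labels)
        assert out.loc["g", "log2_fc"] == 0.0
        assert out.loc["g", "p_value"] == 1.0

    def test_planted_shift_flagged_at_fdr_005(self):
        rng = np.random.default_rng(3)
        cols = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]
        expr = pd.DataFrame(rng.normal(5, 0.1, size=(200, 10)), columns=cols)
        expr.iloc[0, :5] += 2.0
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=cols)
        out = bm.group_differential(expr, labels)
        assert out.iloc[0]["fdr"] < 0.05
        assert out.iloc[0]["log2_fc"] == pytest.approx(2.0, abs=0.2)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        cols = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]
        expr = pd.DataFrame(rng.normal(size=(1000, 10)), columns=cols)
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=cols)
        out = bm.group_differential(expr, labels)
        assert stats.kstest(out["p_value"], "uniform").pvalue > 0.01


class TestTopPathways:
    def test_k_larger_than_collection_returns_all(self):
        ranked = _ranked(np.linspace(1, -1, 20))
        sets = {"A": ranked.genes[:3], "B": ranked.genes[-3:]}
        res = bm.gsea_preranked(ranked, sets, n_perm=50, seed=0)
        assert len(bm.top_pathways(res, k=10)) == 2

    def test_ordering_deterministic_on_rerun(self):
        ranked = _ranked(np.linspace(1, -1, 30))
        rng = np.random.default_rng(4)
        sets = {f"S{i}": list(rng.choice(ranked.genes, 5, replace=False))
                for i in range(8)}
        a = bm.top_pathways(bm.gsea_preranked(ranked, sets, n_perm=100, seed=9))
        b = bm.top_pathways(bm.gsea_preranked(ranked, sets, n_perm=100, seed=9))
        assert list(a.index) == list(b.index)
        pd.testing.assert_frame_equal(a, b)
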