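import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from omicsmeta.enrichment import (
    OraResult,
    enrich_modules,
    filter_module_genes,
    go_ora,
    module_fusion_pvalue,
    prune_redundant_terms,
)
from omicsmeta.io import ModuleCollection


class TestFilterModuleGenes:
    SOURCES = {
        "A": {"GWAS"},
        "B": {"GWAS", "TWAS"},
        "C": {"GWAS", "TWAS", "RVA"},
        "D": {"TWAS"},
    }

    def test_single_source_gene_removed(self):
        mods = ModuleCollection({"M": ["A", "B", "C"]})
        out = filter_module_genes(mods, self.SOURCES)
        assert out["M"] == ["B", "C"]

    def test_all_single_source_module_dropped(self):
        mods = ModuleCollection({"M": ["A", "D"]})
        with pytest.warns(UserWarning, match="dropped"):
            out = filter_module_genes(mods, self.SOURCES)
        assert "M" not in out

    def test_multi_source_module_unchanged(self):
        mods = ModuleCollection({"M": ["B", "C"]})
        assert filter_module_genes(mods, self.SOURCES)["M"] == ["B", "C"]


class TestFusion:
    def test_single_gene_identity(self):
        _, p = module_fusion_pvalue([0.037])
        assert p == pytest.approx(0.037, abs=1e-10)

    def test_two_gene_closed_form(self):
        # each p=0.05 maps to chi2_1 quantile 3.8415; T = 7.683;
        # chi2_2 survival = exp(-T/2)
        T, p = module_fusion_pvalue([0.05, 0.05])
        assert T == pytest.approx(2 * 3.841458820694124, abs=1e-6)
        assert p == pytest.approx(np.exp(-T / 2), abs=1e-10)

    def test_null_modules_uniform(self):
        r = np.random.default_rng(31)
        pvals = [
            module_fusion_pvalue(r.uniform(size=r.integers(3, 20)))[1]
            for _ in range(1000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_reorder_invariance(self, rng):
        p = rng.uniform(size=8)
        _, p1 = module_fusion_pvalue(p)
        _, p2 = module_fusion_pvalue(p[::-1])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_adding_null_gene_no_inflation(self):
        # a p=1 gene adds 0 to T but one df: fused p can only grow
        base = [0.01, 0.02, 0.05]
        _, p1 = module_fusion_pvalue(base)
        _, p2 = module_fusion_pvalue(base + [1.0])
        assert p2 >= p1

    def test_fisher_variant(self):
        p = [0.1, 0.2]
        T, fused = module_fusion_pvalue(p, method="fisher")
        assert T == pytest.approx(-2 * np.sum(np.log(p)))
        assert fused == pytest.approx(stats.chi2.sf(T, 4), rel=1e-10)


class TestEnrichModules:
    def test_null_module_not_significant(self, rng):
        mods = ModuleCollection({"M": [f"g{i}" for i in range(10)]})
        minp = pd.Series(0.5, index=[f"g{i}" for i in range(100)])
        res = enrich_modules(mods, minp, "t")
        assert res[0].p_corrected > 0.9

    def test_bonferroni_arithmetic(self):
        # 13 modules tested; the planted one gets p ~ raw * 13
        genes = [f"g{i}" for i in range(200)]
        r = np.random.default_rng(5)
        minp = pd.Series(r.uniform(size=200), index=genes)
        mods = {f"M{i}": list(r.choice(genes, 8, replace=False)) for i in range(13)}
        res = enrich_modules(ModuleCollection(mods), minp, "t")
        for item in res:
            assert item.p_corrected == pytest.approx(
                min(1.0, item.p_raw * 13), rel=1e-12
            )

    def test_planted_module_ranks_first(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(500)]
            minp = pd.Series(r.uniform(size=500), index=genes)
            planted = list(r.choice(genes, 10, replace=False))
            minp.loc[planted] = r.beta(0.1, 1.0, size=10)
            mods = {
                f"M{i}": list(r.choice(genes, 10, replace=False))
                for i in range(200)
            }
            mods["planted"] = planted
            res = enrich_modules(ModuleCollection(mods), minp, "t")
            if res[0].module == "planted":
                wins += 1
        assert wins >= 18  # >= 90% of seeds

    def test_empirical_null_close_to_analytic_on_uniform(self):
        r = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(400)]
        minp = pd.Series(r.uniform(size=400), index=genes)
        mods = ModuleCollection({"M": list(r.choice(genes, 12, replace=False))})
        analytic = enrich_modules(mods, minp, "t")[0].p_raw
        empirical = enrich_modules(
            mods, minp, "t", empirical_null=True, n_null=20_000, seed=1
        )[0].p_raw
        assert empirical == pytest.approx(analytic, abs=0.03)


class TestOra:
    def test_extreme_table(self):
        # background 20, set 5, module 5, overlap 5: p = 1 / C(20,5)
        genes = [f"g{i}" for i in range(20)]
        go = ModuleCollection({"T": genes[:5]})
        res = go_ora(genes[:5], go, genes)
        assert res[0].p == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        go = ModuleCollection({"T": genes[10:15]})
        res = go_ora(genes[:5], go, genes)
        assert res[0].p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        # exhaustive hypergeometric mass for a small table
        genes = [f"g{i}" for i in range(12)]
        module = genes[:6]
        go = ModuleCollection({"T": genes[3:8]})
        res = go_ora(module, go, genes)
        M, n, N = 12, 5, 6
        k_obs = len(set(module) & set(genes[3:8]))
        from math import comb

        total = comb(M, n)
        mass = sum(
            comb(N, k) * comb(M - N, n - k) for k in range(k_obs, min(n, N) + 1)
        )
        assert res[0].p == pytest.approx(mass / total, rel=1e-9)

    def test_empty_background_raises(self):
        with pytest.raises(ValueError):
            go_ora(["a"], ModuleCollection({"T": ["a"]}), [])

    def test_bh_matches_step_up_oracle(self):
        # 10-term worked example against the hand-computed step-up definition
        pvals = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074,
                          0.205, 0.212, 0.216])
        expected = multipletests(pvals, method="fdr_bh")[1]
        m = len(pvals)
        adj = pvals * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        np.testing.assert_allclose(expected, np.minimum(adj, 1), atol=1e-12)
        # FDR column returned by go_ora is monotone nondecreasing in rank
        genes = [f"g{i}" for i in range(40)]
        r = np.random.default_rng(7)
        go = ModuleCollection(
            {f"T{i}": list(r.choice(genes, 8, replace=False)) for i in range(10)}
        )
        res = go_ora(genes[:12], go, genes)
        fdrs = [x.fdr for x in res]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))


class TestPrune:
    def _res(self, term, p, genes):
        return OraResult(term, len(genes), len(genes), 10, 100, p, p, genes)

    def test_identical_sets_keep_best(self):
        a = self._res("A", 0.001, ["x", "y", "z"])
        b = self._res("B", 0.01, ["x", "y", "z"])
        assert prune_redundant_terms([a, b]) == [a]

    def test_disjoint_all_kept(self):
        a = self._res("A", 0.001, ["x", "y"])
        b = self._res("B", 0.01, ["u", "v"])
        assert prune_redundant_terms([a, b]) == [a, b]

    def test_threshold_one_keeps_all(self):
        a = self._res("A", 0.001, ["x", "y", "z"])
        b = self._res("B", 0.01, ["x", "y", "z"])
        # identical sets have Jaccard exactly 1 > threshold is false at 1.0
        assert prune_redundant_terms([a, b], jaccard_threshold=1.0) == [a, b]
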