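import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicsmeta.cma import (
    combine,
    estimate_null_correlation,
    p_to_z,
    replicate,
    run_cma,
    tetrachoric_correlation,
)


class TestPToZ:
    @pytest.mark.parametrize(
        "p,expected", [(0.5, 0.0), (0.025, 1.9599639845400545)]
    )
    def test_known_values(self, p, expected):
        assert p_to_z(p) == pytest.approx(expected, abs=1e-6)

    def test_boundary_p_one_clipped(self):
        assert p_to_z(1.0) >= -37.0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            p_to_z(0.0)
        with pytest.raises(ValueError):
            p_to_z(1.5)


class TestCombine:
    def test_single_source_identity(self):
        assert combine([p_to_z(0.03)], np.eye(1)) == pytest.approx(0.03, abs=1e-12)

    def test_stouffer_when_independent(self):
        z = p_to_z([0.05, 0.05])
        expected = stats.norm.sf((z[0] + z[1]) / np.sqrt(2))
        assert combine(z, np.eye(2)) == pytest.approx(expected, abs=1e-12)
        assert combine(z, np.eye(2)) == pytest.approx(0.0100, abs=5e-4)

    def test_reduces_to_stouffer_over_many_inputs(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 4))
            p = rng.uniform(0.001, 0.999, k)
            z = p_to_z(p)
            got = combine(z, np.eye(k))
            want = stats.norm.sf(z.sum() / np.sqrt(k))
            assert abs(got - want) < 1e-12

    def test_fully_correlated_identical_inputs(self):
        z = p_to_z([0.05, 0.05])
        got = combine(z, np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert got == pytest.approx(0.05, abs=1e-10)

    def test_missing_entry_returns_observed_source(self):
        z = np.array([np.nan, p_to_z(0.02), np.nan])
        S = np.eye(3)
        assert combine(z, S) == pytest.approx(0.02, abs=1e-12)

    def test_monotone_in_inputs(self, rng):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        for _ in range(100):
            p = rng.uniform(0.01, 0.99, 2)
            base = combine(p_to_z(p), S)
            p2 = p.copy()
            p2[0] *= 0.5
            assert combine(p_to_z(p2), S) <= base + 1e-15


class TestTetrachoric:
    def test_independence_table(self):
        assert tetrachoric_correlation([[25, 25], [25, 25]]) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_perfect_concordance_clipped(self):
        assert tetrachoric_correlation([[50, 0], [0, 50]]) >= 0.99

    def test_matches_grid_search_oracle(self):
        table = np.array([[30, 12], [10, 28]])
        n = table.sum()
        px = table[1].sum() / n
        py = table[:, 1].sum() / n
        hx, hy = stats.norm.isf(px), stats.norm.isf(py)

        def nll(rho):
            p11 = stats.multivariate_normal(
                [0, 0], [[1, rho], [rho, 1]]
            ).cdf([-hx, -hy])
            probs = np.clip(
                [1 - px - py + p11, py - p11, px - p11, p11], 1e-12, 1
            )
            return -np.sum(table.ravel() * np.log(probs))

        grid = np.linspace(-0.995, 0.995, 797)
        best = grid[np.argmin([nll(r) for r in grid])]
        assert tetrachoric_correlation(table) == pytest.approx(best, abs=5e-3)


class TestNullCorrelation:
    def test_duplicated_column_clipped_high(self, rng):
        p = rng.uniform(size=500)
        P = pd.DataFrame({"GWAS": p, "TWAS": p})
        m = estimate_null_correlation(P)
        assert m.sigma[0, 1] >= 0.99

    def test_independent_sources_near_zero(self):
        r = np.random.default_rng(21)
        P = pd.DataFrame(r.uniform(size=(5000, 3)), columns=["GWAS", "TWAS", "RVA"])
        m = estimate_null_correlation(P)
        off = m.sigma[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_small_null_subset_falls_back(self):
        r = np.random.default_rng(22)
        # nearly all genes carry signal -> null subset too small
        P = pd.DataFrame(
            {"GWAS": r.uniform(0, 1e-5, 60), "TWAS": r.uniform(size=60)}
        )
        with pytest.warns(UserWarning, match="null-subset"):
            m = estimate_null_correlation(P)
        assert m.null_mask_rule.startswith("all genes")

    def test_tetrachoric_estimator_on_correlated_sources(self):
        r = np.random.default_rng(23)
        z = r.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=4000)
        P = pd.DataFrame(stats.norm.sf(z), columns=["GWAS", "TWAS"])
        m = estimate_null_correlation(P, estimator="tetrachoric")
        assert m.sigma[0, 1] == pytest.approx(0.5, abs=0.1)


def _score_rows(gene_ids, trait, source, pvals, category="none", betas=None):
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "trait": trait,
            "source": source,
            "category": category,
            "p": pvals,
            "beta": betas if betas is not None else np.nan,
            "n_units": 1,
        }
    )


class TestRunCma:
    def _toy_scores(self, rng, n_genes=300, strong_gene=None):
        genes = [f"g{i}" for i in range(n_genes)]
        frames = [
            _score_rows(genes, "t", "GWAS", rng.uniform(size=n_genes)),
            _score_rows(genes, "t", "TWAS", rng.uniform(size=n_genes)),
        ]
        for cat in ("missense", "plof"):
            frames.append(
                _score_rows(genes, "t", "RVA", rng.uniform(size=n_genes), cat)
            )
        scores = pd.concat(frames, ignore_index=True)
        if strong_gene:
            # one very strong source, GWAS null, no RVA rows for this gene
            scores.loc[
                (scores.gene_id == strong_gene) & (scores.source == "TWAS"), "p"
            ] = 1e-10
            scores.loc[
                (scores.gene_id == strong_gene) & (scores.source == "GWAS"), "p"
            ] = 0.5
            scores = scores[
                ~((scores.gene_id == strong_gene) & (scores.source == "RVA"))
            ]
        return scores

    def test_total_tests_aggregated_over_runs(self, rng):
        scores = self._toy_scores(rng)
        res = run_cma(scores)
        # 10 category runs; every gene has GWAS+TWAS, so each run tests all genes
        assert res.total_tests == 10 * 300
        assert res.threshold == pytest.approx(0.05 / 3000)

    def test_strong_single_source_drives_significance(self, rng):
        res = run_cma(self._toy_scores(rng, strong_gene="g7"))
        assert bool(res.significant["g7"])
        # significant in every category where tested
        assert (res.pvalues.loc["g7"].dropna() < res.threshold).all()

    def test_single_source_errors(self, rng):
        scores = _score_rows([f"g{i}" for i in range(10)], "t", "GWAS",
                             rng.uniform(size=10))
        with pytest.raises(ValueError, match="two sources"):
            run_cma(scores)

    def test_two_traits_rejected(self, rng):
        s1 = self._toy_scores(rng)
        s2 = s1.copy()
        s2["trait"] = "other"
        with pytest.raises(ValueError, match="single trait"):
            run_cma(pd.concat([s1, s2]))


class TestReplicate:
    def test_threshold_arithmetic(self):
        disc = _score_rows([f"g{i}" for i in range(30)], "t", "TWAS",
                           [1e-8] * 30)
        rep = _score_rows(["g0", "g1"], "t", "TWAS", [1e-4, 0.5])
        out = replicate(disc, rep, mode="gene")
        assert out["threshold"].iloc[0] == pytest.approx(0.05 / 30)
        assert bool(out.loc[out.gene_id == "g0", "replicated"].iloc[0])
        assert not bool(out.loc[out.gene_id == "g1", "replicated"].iloc[0])

    def test_direction_concordance(self):
        disc = _score_rows(["g0"], "t", "TWAS", [1e-8], betas=[0.5])
        rep = _score_rows(["g0"], "t", "TWAS", [1e-4], betas=[0.2])
        out = replicate(disc, rep, mode="gene")
        assert bool(out["direction_consistent"].iloc[0])
        rep_neg = _score_rows(["g0"], "t", "TWAS", [1e-4], betas=[-0.2])
        out2 = replicate(disc, rep_neg, mode="gene")
        assert not bool(out2["direction_consistent"].iloc[0])

    def test_empty_discovery_returns_empty(self):
        disc = _score_rows([], "t", "TWAS", [])
        rep = _score_rows(["g0"], "t", "TWAS", [0.01])
        out = replicate(disc, rep, mode="gene")
        assert len(out) == 0

    def test_cma_mode_counts_gene_category_pairs(self):
        disc = pd.DataFrame(
            {
                "gene_id": ["g0", "g0", "g1"],
                "category": ["missense", "plof", "missense"],
                "p": [1e-9, 1e-8, 1e-8],
            }
        )
        rep = pd.DataFrame(
            {
                "gene_id": ["g0", "g1"],
                "category": ["missense", "missense"],
                "p": [1e-3, 0.9],
            }
        )
        out = replicate(disc, rep, mode="cma")
        assert out["threshold"].iloc[0] == pytest.approx(0.05 / 3)
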