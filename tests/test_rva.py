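import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicsmeta.io import VariantRecord
from omicsmeta.rva import (
    annotation_pc_weights,
    combined_weights,
    run_rva,
    skat_test,
)


class TestAnnotationPc:
    def test_single_column_monotone(self, rng):
        col = rng.standard_normal((30, 1))
        apc = annotation_pc_weights(col)
        assert stats.spearmanr(col[:, 0], apc).statistic == pytest.approx(1.0)

    def test_tied_rows_equal_weight(self, rng):
        A = rng.standard_normal((10, 4))
        A[3] = A[7]
        apc = annotation_pc_weights(A)
        assert apc[3] == pytest.approx(apc[7])

    def test_matches_eigendecomposition_oracle(self):
        r = np.random.default_rng(9)
        A = r.standard_normal((50, 6))
        Z = (A - A.mean(axis=0)) / A.std(axis=0)
        evals, evecs = np.linalg.eigh(np.corrcoef(Z.T))
        s = Z @ evecs[:, -1]
        if np.corrcoef(s, Z.mean(axis=1))[0, 1] < 0:
            s = -s
        u = stats.rankdata(s) / 51
        expected = -10 * np.log10(1 - u)
        np.testing.assert_allclose(annotation_pc_weights(A), expected, atol=1e-8)

    def test_constant_annotations_uniform(self):
        with pytest.warns(UserWarning, match="constant"):
            apc = annotation_pc_weights(np.ones((5, 3)))
        assert np.allclose(apc, apc[0])


class TestSkat:
    def test_single_variant_returns_missing(self, rng):
        g = rng.binomial(2, 0.02, 100).astype(float)
        assert skat_test(g[:, None], [1.0], rng.standard_normal(100)) is None

    def test_identical_pair_equals_score_test(self):
        r = np.random.default_rng(10)
        n = 200
        g = r.binomial(2, 0.03, n).astype(float)
        resid = r.standard_normal(n)
        resid -= resid.mean()
        p_skat = skat_test(np.column_stack([g, g]), [1.0, 1.0], resid)
        s2 = resid @ resid / (n - 1)
        gc = g - g.mean()
        chi = (g @ resid / s2) ** 2 / (gc @ gc / s2)
        p_score = stats.chi2.sf(chi, 1)
        assert p_skat == pytest.approx(p_score, rel=1e-6)

    def test_matches_permutation_oracle(self):
        agree = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            n, k = 200, 5
            G = r.binomial(2, r.uniform(0.01, 0.05, k), (n, k)).astype(float)
            resid = r.standard_normal(n)
            resid -= resid.mean()
            p = skat_test(G, np.ones(k), resid)
            s2 = resid @ resid / (n - 1)
            q_obs = np.sum((G.T @ (resid / s2)) ** 2)
            nperm = 5000
            perms = np.array([r.permutation(resid) for _ in range(nperm)])
            qs = np.sum(((perms / s2) @ G) ** 2, axis=1)
            p_perm = (1 + np.sum(qs >= q_obs)) / (nperm + 1)
            se = np.sqrt(p_perm * (1 - p_perm) / nperm)
            if abs(p - p_perm) < 3 * max(se, 1e-3):
                agree += 1
        assert agree >= 4

    def test_weight_scaling_invariance(self):
        r = np.random.default_rng(11)
        n, k = 150, 4
        G = r.binomial(2, 0.03, (n, k)).astype(float)
        resid = r.standard_normal(n)
        w = r.uniform(0.5, 2.0, k)
        p1 = skat_test(G, w, resid)
        p2 = skat_test(G, 10.0 * w, resid)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_textbook_skat_dense_crosscheck(self):
        # w = 1, no kinship: compare against a direct dense implementation
        r = np.random.default_rng(12)
        n, k = 120, 6
        G = r.binomial(2, 0.04, (n, k)).astype(float)
        resid = r.standard_normal(n)
        resid -= resid.mean()
        p = skat_test(G, np.ones(k), resid)

        from omicsmeta.gwas import quadform_tail

        s2 = resid @ resid / (n - 1)
        Q = resid @ G @ G.T @ resid / s2**2
        H = np.eye(n) - np.full((n, n), 1.0 / n)
        lam = np.linalg.eigvalsh(G.T @ H @ G / s2)
        p_direct = quadform_tail(Q, np.clip(lam, 0, None))
        assert p == pytest.approx(p_direct, rel=1e-6)


class TestRunRva:
    def _variants(self, rng, n, cats_sizes):
        variants, cats = [], {}
        pos = 1000
        for cat, size in cats_sizes.items():
            for j in range(size):
                vid = f"{cat}_{j}"
                d = rng.binomial(2, 0.03, n).astype(float)
                variants.append(VariantRecord(vid, "1", pos, "A", "T", d))
                cats[vid] = cat
                pos += 10
        return variants, cats

    def test_min_two_variant_rule(self, rng):
        n = 150
        variants, cats = self._variants(rng, n, {"missense": 3, "UTR": 1})
        ann = pd.DataFrame(
            rng.standard_normal((len(variants), 4)),
            index=[v.variant_id for v in variants],
        )
        out = run_rva("g", variants, cats, ann, rng.standard_normal(n), None, "t")
        assert list(out["category"]) == ["missense"]
        assert out["n_units"].iloc[0] == 3

    def test_unknown_category_rejected(self, rng):
        n = 50
        variants, cats = self._variants(rng, n, {"missense": 2})
        cats[variants[0].variant_id] = "bogus"
        ann = pd.DataFrame(
            rng.standard_normal((len(variants), 3)),
            index=[v.variant_id for v in variants],
        )
        with pytest.raises(ValueError, match="category"):
            run_rva("g", variants, cats, ann, rng.standard_normal(n), None, "t")

    def test_null_calibration_across_genes(self):
        r = np.random.default_rng(13)
        n = 300
        pvals = []
        resid = r.standard_normal(n)
        resid -= resid.mean()
        for _ in range(300):
            k = int(r.integers(2, 6))
            G = r.binomial(2, r.uniform(0.01, 0.05, k), (n, k)).astype(float)
            A = r.standard_normal((k, 4))
            w = combined_weights([f"v{i}" for i in range(k)],
                                 G.mean(axis=0) / 2, A)
            p = skat_test(G, w.w, resid)
            if p is not None:
                pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_category_found(self):
        # burden planted in plof: plof row should usually have the smallest p
        wins = 0
        n = 400
        for seed in range(15):
            r = np.random.default_rng(200 + seed)
            variants, cats = self._variants(
                r, n, {"plof": 4, "missense": 4, "UTR": 4}
            )
            plof_burden = sum(
                v.dosages for v in variants if cats[v.variant_id] == "plof"
            )
            resid = 0.6 * (plof_burden - plof_burden.mean()) + r.standard_normal(n)
            resid -= resid.mean()
            ann = pd.DataFrame(
                r.standard_normal((len(variants), 4)),
                index=[v.variant_id for v in variants],
            )
            out = run_rva("g", variants, cats, ann, resid, None, "t")
            best = out.loc[out["p"].idxmin(), "category"]
            if best == "plof":
                wins += 1
        assert wins >= 12  # >= 80%
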