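"""Rare-variant gene tests: per-category variant sets with
annotation-informed weights and a kinship-aware SKAT.

Rare variants (MAF < 5%) near a gene are split into ten functional
categories; each category with at least two variants gets a SKAT
variance-component test. Variant weights combine the classic
Beta(MAF; 1, 25) density with a Phred-scaled first principal component of
the standardized functional annotation scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import quadform_tail
from .io import RVA_CATEGORIES, VariantRecord
from .lmm import VarianceModel

__all__ = [
    "MIN_VARIANTS",
    "annotation_pc_weights",
    "combined_weights",
    "skat_test",
    "run_rva",
    "run_rva_all",
]

#: A category is testable only with at least this many variants.
MIN_VARIANTS = 2
#: MAF cut separating rare from common variants.
RARE_MAF_MAX = 0.05


@dataclass
class VariantWeight:
    variant_ids: list[str]
    apc: np.ndarray  # Phred-scale annotation PC score
    maf_beta: np.ndarray  # Beta(MAF; 1, 25) density factor
    w: np.ndarray  # combined weight, > 0


def annotation_pc_weights(A) -> np.ndarray:
    """Phred-scaled first-PC score of standardized annotation columns.

    Columns are standardized to mean 0, sd 1 (constant columns dropped);
    the first principal-component score is sign-oriented to correlate
    positively with the row mean of the standardized matrix; scores are
    converted to upper-tail percentiles u = rank/(n+1) (average ranks) and
    Phred-scaled as -10*log10(1 - u). All-constant annotations yield
    uniform scores with a warning.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 variants")
    sd = A.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.any():
        warnings.warn("all annotation columns constant; uniform weights")
        return np.full(n, -10 * np.log10(1 - 0.5))
    Z = (A[:, keep] - A[:, keep].mean(axis=0)) / sd[keep]
    _u, _s, vt = np.linalg.svd(Z, full_matrices=False)
    s1 = Z @ vt[0]
    rowmean = Z.mean(axis=1)
    if np.dot(s1 - s1.mean(), rowmean - rowmean.mean()) < 0:
        s1 = -s1
    u = stats.rankdata(s1, method="average") / (n + 1)
    return -10.0 * np.log10(1.0 - u)


def combined_weights(variant_ids, mafs, annotations) -> VariantWeight:
    """STAAR-style combined weight: w_j^2 = Beta(MAF_j;1,25)^2 * aPC_j/mean(aPC)."""
    mafs = np.asarray(mafs, dtype=float)
    apc = annotation_pc_weights(annotations)
    maf_beta = stats.beta.pdf(mafs, 1, 25)
    w = maf_beta * np.sqrt(apc / apc.mean())
    w = np.maximum(w, 1e-12)
    return VariantWeight(list(variant_ids), apc, maf_beta, w)


def skat_test(G, w, r, vm: VarianceModel | None = None):
    """SKAT variance-component p-value for one variant set.

    ``G`` is samples x variants of dosages (missing mean-imputed), ``w``
    per-variant weights, ``r`` the prepared trait residual, ``vm`` the
    trait's variance model (None = independent samples). The statistic is
    Q = r' V^-1 G W^2 G' V^-1 r with null distribution the chi-square
    mixture weighted by the eigenvalues of W G' P0 G W. Returns None for
    fewer than 2 variants (the set is not testable).
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.ndim == 1:
        G = G[:, None]
    n, k = G.shape
    if k < MIN_VARIANTS:
        return None
    r = np.asarray(r, dtype=float)
    if len(r) != n:
        raise ValueError("residual length does not match genotype rows")
    w = np.asarray(w, dtype=float)
    if len(w) != k:
        raise ValueError("weight length does not match variant count")
    Gi = G.copy()
    for j in range(k):
        miss = np.isnan(Gi[:, j])
        if miss.any():
            Gi[miss, j] = np.nanmean(Gi[:, j])

    if vm is None:
        s2 = float(r @ r) / (n - 1)
        vinv_r = r / s2
        GW = Gi * w
        Q = float(np.sum((GW.T @ vinv_r) ** 2))
        Gc = GW - GW.mean(axis=0)
        M = (Gc.T @ Gc) / s2
    else:
        vinv_r = vm.solve(r)
        GW = Gi * w
        Q = float(np.sum((GW.T @ vinv_r) ** 2))
        P0 = vm.null_projection()
        M = GW.T @ P0 @ GW
    lam = np.clip(np.linalg.eigvalsh(0.5 * (M + M.T)), 0.0, None)
    if lam.sum() <= 0:
        return None
    return quadform_tail(Q, lam)


def run_rva(
    gene_id: str,
    variants: list[VariantRecord],
    categories: dict[str, str],
    annotations: pd.DataFrame,
    r,
    vm: VarianceModel | None,
    trait: str,
) -> pd.DataFrame:
    """All category tests for one gene's rare variants.

    ``variants`` are the gene's rare variants (already windowed and
    MAF-filtered), ``categories`` maps variant id -> functional category,
    ``annotations`` is the variant x annotation score matrix. Weights (and
    their annotation PC) are computed within each tested category. Emits
    one gene-score row per category with >= 2 variants.
    """
    rows = []
    by_cat: dict[str, list[VariantRecord]] = {}
    for v in variants:
        cat = categories.get(v.variant_id)
        if cat is None:
            continue
        if cat not in RVA_CATEGORIES:
            raise ValueError(f"unknown functional category {cat!r}")
        by_cat.setdefault(cat, []).append(v)
    for cat in RVA_CATEGORIES:
        vs = by_cat.get(cat, [])
        if len(vs) < MIN_VARIANTS:
            continue
        ids = [v.variant_id for v in vs]
        A = annotations.loc[ids].to_numpy(dtype=float)
        vw = combined_weights(ids, [v.maf for v in vs], A)
        G = np.column_stack([v.dosages for v in vs])
        p = skat_test(G, vw.w, r, vm)
        if p is None:
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "trait": trait,
                "source": "RVA",
                "category": cat,
                "p": p,
                "beta": np.nan,
                "n_units": len(vs),
            }
        )
    return pd.DataFrame(rows)


def run_rva_all(
    genes,
    variants: list[VariantRecord],
    categories: dict[str, str],
    annotations: pd.DataFrame,
    r,
    vm: VarianceModel | None,
    trait: str,
    *,
    window: int = 50_000,
    maf_max: float = RARE_MAF_MAX,
) -> pd.DataFrame:
    """Rare-variant stage over all genes (same +/-50 kb windowing as the
    common-variant aggregation, MAF < ``maf_max``)."""
    from .gwas import assign_snps_to_genes

    rare = [v for v in variants if 0.0 < v.maf < maf_max]
    assign = assign_snps_to_genes(rare, genes, window=window)
    vmap = {v.variant_id: v for v in rare}
    out = []
    for g in genes:
        vs = [vmap[vid] for vid in assign.assignments.get(g.gene_id, [])]
        if not vs:
            continue
        df = run_rva(g.gene_id, vs, categories, annotations, r, vm, trait)
        if len(df):
            out.append(df)
    if not out:
        return pd.DataFrame(
            columns=["gene_id", "trait", "source", "category", "p", "beta", "n_units"]
        )
    return pd.concat(out, ignore_index=True)
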