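"""Module enrichment on meta-analysis gene p-values and GO
over-representation of enriched-module genes.

A protein-interaction module is scored by fusing its genes' p-values into
a chi-square sum: T = sum_g Qchi2_1(1 - p_g), referenced to chi2 with k
degrees of freedom. Because the input per gene is the *minimum* over ten
category runs (anti-conservative), a size-matched random-set empirical
null is the recommended mode for headline calls; the analytic tail is kept
for speed and unit checks. Enriched-module genes are then tested for GO
biological-process over-representation with a hypergeometric test and BH
control, and near-duplicate terms are pruned greedily by Jaccard overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ModuleCollection

__all__ = [
    "EnrichmentResult",
    "OraResult",
    "filter_module_genes",
    "module_fusion_pvalue",
    "enrich_modules",
    "go_ora",
    "prune_redundant_terms",
]


@dataclass
class EnrichmentResult:
    module: str
    trait: str
    statistic: float
    p_raw: float
    p_corrected: float
    n_genes: int
    member_minp: dict


@dataclass
class OraResult:
    term: str
    overlap: int
    set_size: int
    module_size: int
    background_size: int
    p: float
    fdr: float
    genes: list


def filter_module_genes(
    modules: ModuleCollection, sources_per_gene: dict[str, set]
) -> ModuleCollection:
    """Drop module genes supported by fewer than two sources.

    Genes with evidence from only one of GWAS/TWAS/RVA are removed from
    every module; modules left with fewer than 2 genes are dropped with a
    warning.
    """
    out = {}
    for name, genes in modules.items():
        kept = [g for g in genes if len(sources_per_gene.get(g, ())) >= 2]
        if len(kept) < 2:
            warnings.warn(f"module {name!r} dropped ({len(kept)} multi-source gene(s))")
            continue
        out[name] = kept
    return ModuleCollection(out, provenance=modules.provenance)


def module_fusion_pvalue(pvals, *, method: str = "chi2"):
    """Fuse a module's gene p-values into one enrichment p.

    method="chi2" (default): T = sum_g Qchi2_1(1 - p_g) referenced to
    chi2_k. method="fisher": T = -2 sum log p referenced to chi2_2k.
    Returns (statistic, p).
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "chi2":
        T = float(np.sum(stats.chi2.isf(p, df=1)))
        return T, float(stats.chi2.sf(T, df=len(p)))
    if method == "fisher":
        T = float(-2 * np.sum(np.log(p)))
        return T, float(stats.chi2.sf(T, df=2 * len(p)))
    raise ValueError(f"unknown fusion method {method!r}")


def enrich_modules(
    modules: ModuleCollection,
    gene_minp: pd.Series,
    trait: str,
    *,
    method: str = "chi2",
    correction: str = "bonferroni",
    empirical_null: bool = False,
    n_null: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Enrichment p per module, corrected over the modules tested.

    Genes absent from ``gene_minp`` are ignored. With
    ``empirical_null=True`` the raw p is the fraction of ``n_null``
    size-matched random gene sets (drawn from the tested universe) whose
    fusion statistic is at least the observed one — this calibrates away
    the anti-conservativeness of min-over-categories inputs. ``correction``
    is "bonferroni" (default) or "bh".
    """
    universe = gene_minp.dropna()
    rng = np.random.default_rng(seed)
    logq_all = stats.chi2.isf(universe.to_numpy(), df=1)

    tested: list[tuple[str, list, float, float]] = []
    for name, genes in modules.items():
        member = [g for g in genes if g in universe.index]
        if len(member) < 2:
            continue
        pv = universe.loc[member].to_numpy()
        T, p_raw = module_fusion_pvalue(pv, method=method)
        if empirical_null:
            k = len(member)
            draws = rng.choice(len(logq_all), size=(n_null, k))
            null_T = logq_all[draws].sum(axis=1)
            p_raw = (1.0 + np.sum(null_T >= T)) / (n_null + 1.0)
        tested.append((name, member, T, p_raw))

    n_tested = len(tested)
    raw = np.array([t[3] for t in tested])
    if correction == "bonferroni":
        corr = np.minimum(1.0, raw * n_tested)
    elif correction == "bh":
        corr = multipletests(raw, method="fdr_bh")[1] if n_tested else raw
    else:
        raise ValueError(f"unknown correction {correction!r}")

    results = []
    for (name, member, T, p_raw), p_c in zip(tested, corr):
        results.append(
            EnrichmentResult(
                module=name,
                trait=trait,
                statistic=T,
                p_raw=float(p_raw),
                p_corrected=float(p_c),
                n_genes=len(member),
                member_minp={g: float(universe.loc[g]) for g in member},
            )
        )
    results.sort(key=lambda r: r.p_raw)
    return results


def go_ora(
    module_genes,
    go_sets: ModuleCollection,
    background,
    *,
    fdr_threshold: float = 0.05,
) -> list[OraResult]:
    """Hypergeometric over-representation of GO sets in a gene list.

    The background is the tested gene universe (it must contain the module
    genes); GO sets are intersected with it. p = P(overlap >= observed)
    under the hypergeometric law; BH FDR across terms.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    mod = set(module_genes) & bg
    M = len(bg)
    N = len(mod)
    rows = []
    for term, genes in go_sets.items():
        gset = set(genes) & bg
        if not gset:
            continue
        k = len(gset & mod)
        n = len(gset)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        rows.append((term, k, n, sorted(gset & mod), p))
    if not rows:
        return []
    pvals = np.array([r[4] for r in rows])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = [
        OraResult(term, k, n, N, M, p, float(q), genes)
        for (term, k, n, genes, p), q in zip(rows, fdr)
    ]
    out.sort(key=lambda r: r.p)
    return out


def prune_redundant_terms(results: list[OraResult], jaccard_threshold: float = 0.5):
    """Greedy pruning of overlapping GO terms.

    Results must be sorted by p ascending (as returned by go_ora); a term
    is kept iff its member-gene Jaccard index with every already-kept term
    is <= the threshold.
    """
    kept: list[OraResult] = []
    for r in results:
        genes = set(r.genes)
        ok = True
        for k in kept:
            kg = set(k.genes)
            union = genes | kg
            if union and len(genes & kg) / len(union) > jaccard_threshold:
                ok = False
                break
        if ok:
            kept.append(r)
    return kept
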