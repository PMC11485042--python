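"""Correlated meta-analysis (CMA) of gene-level evidence.

Gene p-values from the common-variant aggregation (GWAS), measured
expression association (TWAS) and one rare-variant category (RVA) are
converted to upper-tail z-scores and combined as a Stouffer sum whose
standard deviation uses an inter-source correlation matrix estimated
empirically under the null. Because the rare-variant stage yields ten
category p-values per gene, the meta-analysis runs once per category; the
Bonferroni accounting aggregates test counts over all ten runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import RVA_CATEGORIES, clip_pvalues

__all__ = [
    "CorrelationModel",
    "CmaResult",
    "p_to_z",
    "tetrachoric_correlation",
    "estimate_null_correlation",
    "combine",
    "run_cma",
    "replicate",
]

#: z-scores are clipped to +/- this, matching the p-value floor.
Z_CLIP = 37.0
#: Genes with every source p above this form the null subset for
#: correlation estimation.
NULL_P_MIN = 1e-4
#: Minimum null-subset size before falling back to all genes.
MIN_NULL_GENES = 50


@dataclass
class CorrelationModel:
    """K x K inter-source correlation estimated under the null."""

    sources: list[str]
    sigma: np.ndarray
    estimator: str
    n_genes: int
    null_mask_rule: str = f"all sources p > {NULL_P_MIN}"


@dataclass
class CmaResult:
    """Per-category combined p-values with aggregated-Bonferroni calls."""

    pvalues: pd.DataFrame  # genes x categories
    min_p: pd.Series
    argmin_category: pd.Series
    total_tests: int
    alpha: float
    correlations: dict[str, CorrelationModel] = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        return self.alpha / self.total_tests

    @property
    def significant(self) -> pd.Series:
        return self.min_p < self.threshold

    def to_frame(self, trait: str) -> pd.DataFrame:
        """Long-format gene-score rows (source="CMA") plus call columns."""
        long = self.pvalues.stack().rename("p").reset_index()
        long.columns = ["gene_id", "category", "p"]
        long["trait"] = trait
        long["source"] = "CMA"
        long["beta"] = np.nan
        long["n_units"] = 1
        long["min_p_flag"] = [
            c == self.argmin_category[g] for g, c in zip(long["gene_id"], long["category"])
        ]
        long["significant"] = [
            bool(self.significant[g]) and p < self.threshold
            for g, p in zip(long["gene_id"], long["p"])
        ]
        return long


def p_to_z(p):
    """Upper-tail, direction-free z: z = Phi^-1(1 - p), clipped to +/-37.

    Signs from the underlying tests are not commensurable across sources
    (rare-variant and sum-of-chi-square tests are unsigned), so the
    meta-analysis works on evidence magnitude only.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr[~np.isnan(arr)] <= 0) | (arr[~np.isnan(arr)] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    z = stats.norm.isf(clip_pvalues(arr))
    z = np.clip(z, -Z_CLIP, Z_CLIP)
    return np.where(np.isnan(arr), np.nan, z)


def tetrachoric_correlation(table) -> float:
    """MLE of the latent bivariate-normal correlation from a 2x2 table.

    Thresholds come from the marginal proportions; the correlation is found
    by a bounded 1-D likelihood search over the quadrant probability.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or t.sum() <= 0:
        raise ValueError("need a non-empty 2x2 table")
    n = t.sum()
    # zero cells: continuity correction
    if (t == 0).any():
        t = t + 0.5
        n = t.sum()
    px = (t[1, 0] + t[1, 1]) / n  # P(X high)
    py = (t[0, 1] + t[1, 1]) / n  # P(Y high)
    hx = stats.norm.isf(px)
    hy = stats.norm.isf(py)

    def quadrant(rho):
        # P(X > hx, Y > hy) under standard bivariate normal
        cov = np.array([[1.0, rho], [rho, 1.0]])
        return stats.multivariate_normal(mean=[0, 0], cov=cov, allow_singular=True).cdf(
            [-hx, -hy]
        )

    def nll(rho):
        p11 = quadrant(rho)
        p10 = px - p11
        p01 = py - p11
        p00 = 1 - p11 - p10 - p01
        probs = np.array([p00, p01, p10, p11])
        probs = np.clip(probs, 1e-12, 1.0)
        counts = np.array([t[0, 0], t[0, 1], t[1, 0], t[1, 1]])
        return -float(counts @ np.log(probs))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded")
    return float(np.clip(res.x, -0.99, 0.99))


def _psd_correlation(S: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at zero and rescale to unit diagonal."""
    S = 0.5 * (S + S.T)
    lam, U = np.linalg.eigh(S)
    S = (U * np.clip(lam, 0.0, None)) @ U.T
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


def estimate_null_correlation(
    P: pd.DataFrame, estimator: str = "pearson"
) -> CorrelationModel:
    """Inter-source correlation from a gene x source p-value matrix.

    Signal genes would inflate the correlation, so estimation is restricted
    to the null subset (all observed sources p > 1e-4); if fewer than 50
    such genes exist, all genes are used with a warning. ``estimator`` is
    "pearson" (on z-scores, pairwise complete) or "tetrachoric"
    (median-dichotomized z). Off-diagonals are clipped to [-0.99, 0.99] and
    the matrix is made PSD by eigenvalue clipping.
    """
    sources = list(P.columns)
    Z = pd.DataFrame(p_to_z(P.to_numpy()), index=P.index, columns=sources)
    obs = P.notna()
    null_mask = ((P > NULL_P_MIN) | ~obs).all(axis=1) & obs.any(axis=1)
    rule = f"all sources p > {NULL_P_MIN}"
    if null_mask.sum() < MIN_NULL_GENES:
        warnings.warn(
            f"only {int(null_mask.sum())} null-subset genes; using all genes"
        )
        null_mask = obs.any(axis=1)
        rule = "all genes (null subset too small)"
    Zn = Z.loc[null_mask]

    K = len(sources)
    S = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            pair = Zn.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                rho = 0.0
            elif estimator == "pearson":
                rho = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
                if not np.isfinite(rho):
                    rho = 0.0
            elif estimator == "tetrachoric":
                x = pair.iloc[:, 0].to_numpy()
                y = pair.iloc[:, 1].to_numpy()
                xh = x > np.median(x)
                yh = y > np.median(y)
                table = [
                    [np.sum(~xh & ~yh), np.sum(~xh & yh)],
                    [np.sum(xh & ~yh), np.sum(xh & yh)],
                ]
                rho = tetrachoric_correlation(table)
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            S[i, j] = S[j, i] = float(np.clip(rho, -0.99, 0.99))
    S = _psd_correlation(S)
    return CorrelationModel(sources, S, estimator, int(null_mask.sum()), rule)


def combine(z, model: CorrelationModel | np.ndarray):
    """Combined p for one gene: p = 1 - Phi(sum(z_S) / sqrt(1' Sigma_SS 1))
    over the observed subset S of sources. A single observed source returns
    its own p exactly."""
    z = np.asarray(z, dtype=float)
    Sigma = model.sigma if isinstance(model, CorrelationModel) else np.asarray(model)
    obs = ~np.isnan(z)
    if not obs.any():
        raise ValueError("no observed sources for this gene")
    zs = z[obs]
    Ss = Sigma[np.ix_(obs, obs)]
    var = float(np.ones(len(zs)) @ Ss @ np.ones(len(zs)))
    if var <= 0:
        Ss = _psd_correlation(Ss)
        var = max(float(np.ones(len(zs)) @ Ss @ np.ones(len(zs))), 1e-12)
    return float(np.clip(stats.norm.sf(zs.sum() / np.sqrt(var)), 1e-300, 1.0))


def run_cma(
    scores: pd.DataFrame,
    *,
    alpha: float = 0.05,
    estimator: str = "pearson",
    categories=RVA_CATEGORIES,
) -> CmaResult:
    """Ten-run correlated meta-analysis for one trait.

    ``scores`` holds gene-score rows from the three sources. Each run pairs
    the GWAS and TWAS columns with one rare-variant category; genes missing
    a source in a run are combined over their observed sources. The
    Bonferroni threshold divides ``alpha`` by the total number of gene
    tests summed over all runs.
    """
    traits = scores["trait"].unique()
    if len(traits) > 1:
        raise ValueError("run_cma expects a single trait")
    present_sources = set(scores["source"]) & {"GWAS", "TWAS", "RVA"}
    if len(present_sources) < 2:
        raise ValueError("need at least two sources for meta-analysis")

    base = {}
    for src in ("GWAS", "TWAS"):
        sub = scores[scores["source"] == src]
        base[src] = sub.set_index("gene_id")["p"]
    rva = scores[scores["source"] == "RVA"]

    per_cat_p: dict[str, pd.Series] = {}
    correlations: dict[str, CorrelationModel] = {}
    total_tests = 0
    for cat in categories:
        cols = {}
        for src in ("GWAS", "TWAS"):
            if src in present_sources:
                cols[src] = base[src]
        sub = rva[rva["category"] == cat]
        if len(sub):
            cols["RVA"] = sub.set_index("gene_id")["p"]
        P = pd.DataFrame(cols)
        P = P.loc[P.notna().any(axis=1)]
        if P.shape[1] < 1 or len(P) == 0:
            continue
        model = estimate_null_correlation(P, estimator=estimator)
        Z = p_to_z(P.to_numpy())
        pvals = np.array([combine(Z[i], model) for i in range(len(P))])
        per_cat_p[cat] = pd.Series(pvals, index=P.index)
        correlations[cat] = model
        total_tests += len(P)

    pmat = pd.DataFrame(per_cat_p)
    min_p = pmat.min(axis=1)
    argmin = pmat.idxmin(axis=1)
    return CmaResult(pmat, min_p, argmin, total_tests, alpha, correlations)


def replicate(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    mode: str = "gene",
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-cohort replication calls.

    ``discovery`` holds the discovery-significant rows (gene_id, and
    category for mode="cma"); ``replication`` the second cohort's scores.
    The replication threshold is alpha divided by the number of
    discovery-significant genes (mode="gene", for GWAS/TWAS) or
    gene-category pairs (mode="cma", for CMA/RVA). For rows with betas on
    both sides, direction concordance is reported.
    """
    if mode not in ("gene", "cma"):
        raise ValueError("mode must be 'gene' or 'cma'")
    if len(discovery) == 0:
        return pd.DataFrame(
            columns=["gene_id", "category", "p_replication", "threshold",
                     "replicated", "direction_consistent"]
        )
    if mode == "gene":
        n_tests = discovery["gene_id"].nunique()
        keys = ["gene_id"]
    else:
        n_tests = len(discovery[["gene_id", "category"]].drop_duplicates())
        keys = ["gene_id", "category"]
    threshold = alpha / n_tests

    rep = replication.copy()
    merged = discovery.merge(rep, on=keys, how="left", suffixes=("_disc", "_rep"))
    p_rep = merged.get("p_rep", merged.get("p"))
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "category": merged["category_disc"] if "category_disc" in merged else
            merged.get("category", "none"),
            "p_replication": p_rep,
            "threshold": threshold,
            "replicated": p_rep.notna() & (p_rep < threshold),
        }
    )
    if "beta_disc" in merged and "beta_rep" in merged:
        out["direction_consistent"] = (
            np.sign(merged["beta_disc"]) == np.sign(merged["beta_rep"])
        ) & merged["beta_disc"].notna() & merged["beta_rep"].notna()
    else:
        out["direction_consistent"] = np.nan
    return out
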