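"""Gene-level aggregation of common-variant GWAS summary statistics.

Per-variant two-sided p-values within a window around each gene body are
converted to squared z-scores and summed; under the null the sum is
distributed as a weighted mixture of 1-df chi-squares whose weights are the
eigenvalues of the local LD (dosage correlation) matrix. The tail
probability of that mixture gives the gene-level p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, VariantRecord, clip_pvalues

__all__ = [
    "SnpGeneAssignment",
    "LdMatrix",
    "assign_snps_to_genes",
    "ld_correlation",
    "quadform_tail",
    "gene_sum_test",
    "single_variant_gwas",
    "run_gwas_aggregation",
]

#: |z| cap keeping z**2 finite for p-values at the 1e-300 clip.
Z_CAP = 37.0
#: Diagonal shrinkage guaranteeing a PSD LD matrix.
LD_SHRINKAGE = 1e-3
#: Eigen-decomposition cost cap; genes beyond this are thinned by MAF.
MAX_VARIANTS_PER_GENE = 3000


@dataclass
class SnpGeneAssignment:
    """gene_id -> variant ids within ``window_bp`` of the gene body."""

    assignments: dict[str, list[str]]
    window_bp: int


@dataclass
class LdMatrix:
    variant_ids: list[str]
    R: np.ndarray
    shrinkage: float = LD_SHRINKAGE


def assign_snps_to_genes(
    variants, genes, window: int = 50_000
) -> SnpGeneAssignment:
    """Assign each variant to every gene whose body +/- ``window`` bp
    contains it (inclusive boundaries; a variant may map to many genes)."""
    by_chrom: dict[str, list] = {}
    for v in variants:
        vid, chrom, pos = (
            (v.variant_id, v.chrom, v.pos) if isinstance(v, VariantRecord) else v[:3]
        )
        by_chrom.setdefault(str(chrom), []).append((int(pos), str(vid)))
    sorted_chrom: dict[str, tuple] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        sorted_chrom[chrom] = (
            np.array([p for p, _ in pairs]),
            [vid for _, vid in pairs],
        )
    out: dict[str, list[str]] = {}
    for g in genes:
        entry = sorted_chrom.get(str(g.chrom))
        if entry is None:
            out[g.gene_id] = []
            continue
        positions, ids = entry
        lo = int(np.searchsorted(positions, g.start - window, side="left"))
        hi = int(np.searchsorted(positions, g.end + window, side="right"))
        out[g.gene_id] = ids[lo:hi]
    return SnpGeneAssignment(out, window)


def ld_correlation(dosages, variant_ids=None, shrinkage: float = LD_SHRINKAGE) -> LdMatrix:
    """Pairwise Pearson correlation of mean-imputed dosages.

    ``dosages`` is variants x samples. Zero-variance variants are dropped
    with a warning. The result is shrunk toward the identity,
    R <- (1-eps) R + eps I, which keeps it PSD under finite-sample noise.
    """
    D = np.atleast_2d(np.asarray(dosages, dtype=float)).copy()
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(D.shape[0])]
    # mean-impute missing calls per variant (imputation is confined to
    # test statistics; MAF is always computed on observed calls)
    for i in range(D.shape[0]):
        miss = np.isnan(D[i])
        if miss.any():
            D[i, miss] = np.nanmean(D[i])
    keep = D.std(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance variant(s)")
    D = D[keep]
    ids = [v for v, k in zip(variant_ids, keep) if k]
    if D.shape[0] == 0:
        raise ValueError("no variants with nonzero variance")
    R = np.corrcoef(D) if D.shape[0] > 1 else np.ones((1, 1))
    R = np.atleast_2d(R)
    R = (1.0 - shrinkage) * R + shrinkage * np.eye(R.shape[0])
    return LdMatrix(ids, R, shrinkage)


def _liu_tail(t: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching approximation to P(sum lam_j X_j > t)."""
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    mu_x = dof + delta
    sigma_x = np.sqrt(2 * (dof + 2 * delta))
    t_star = (t - c1) / np.sqrt(2 * c2)
    q = t_star * sigma_x + mu_x
    return float(stats.ncx2.sf(q, dof, delta) if delta > 0 else stats.chi2.sf(q, dof))


def quadform_tail(t: float, eigenvalues, *, return_method: bool = False):
    """Upper-tail probability P(sum_j lam_j chi2_1 > t).

    Computed by numerical inversion of the characteristic function (Imhof's
    integral, adaptive quadrature, absolute error ~1e-10). If the inversion
    fails or returns a non-positive value, the Liu-Tang-Zhang
    moment-matching approximation is used instead; the method actually used
    is reported when ``return_method`` is set.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-12 * max(1.0, float(np.max(lam, initial=0.0)))]
    if lam.size == 0 or lam.sum() <= 0:
        raise ValueError("need at least one positive eigenvalue")
    if t <= 0:
        return (1.0, "exact") if return_method else 1.0
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        # equal weights: plain (scaled) chi-square survival, exact
        p = float(stats.chi2.sf(t / lam[0], df=lam.size))
        return (p, "exact") if return_method else p

    method = "imhof"
    p = _imhof_midpoint(t, lam)
    if not np.isfinite(p) or p <= 1e-12 or p > 1 + 1e-8:
        p = _liu_tail(t, lam)
        method = "liu"
    p = float(min(max(p, 1e-300), 1.0))
    return (p, method) if return_method else p


def _imhof_midpoint(t: float, lam: np.ndarray, eps: float = 1e-9) -> float:
    """Imhof's inversion integral by a vectorized midpoint rule.

    P(Q > t) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du with
    theta(u) = (1/2) sum_j arctan(lam_j u) - t u / 2 and
    rho(u) = prod_j (1 + lam_j^2 u^2)^(1/4).

    The step keeps the aliasing period far beyond the distribution's mass
    (mean + 40 sd); the truncation point U uses the oscillatory tail bound
    |int_U^inf| <= 2 E(U) / |theta'| with envelope E(u) = 1/(u rho(u)) and
    theta' -> -t/2, so polynomially decaying envelopes still truncate early.
    """
    mu = float(lam.sum())
    sd = float(np.sqrt(2.0 * np.sum(lam**2)))
    delta = 2.0 * np.pi / (t + mu + 40.0 * sd)

    def envelope(u: float) -> float:
        return 1.0 / (u * np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2))))

    U = delta
    while 4.0 * envelope(U) / t > eps and U < 1e12:
        U *= 2.0
    # the tail bound is conservative (alternating-series remainders are far
    # smaller); capping the point count keeps k=2 sets fast while the
    # oscillatory tail at the cap stays below ~1e-8
    n_total = min(int(U / delta) + 1, 200_000)

    total = 0.0
    chunk = 262_144
    start = 0
    while start < n_total:
        u = (np.arange(start, min(start + chunk, n_total)) + 0.5) * delta
        M = u[:, None] * lam
        theta = 0.5 * np.arctan(M).sum(axis=1) - 0.5 * t * u
        log_rho = 0.25 * np.log1p(M * M).sum(axis=1)
        total += float(np.sum(np.sin(theta) * np.exp(-log_rho) / u))
        start += chunk
    return 0.5 + total * delta / np.pi


def gene_sum_test(pvals, ld: LdMatrix | np.ndarray):
    """Gene-level p-value from per-variant two-sided p-values.

    T = sum_i z_i^2 with |z_i| = Phi^-1(1 - p_i/2) capped at 37; the null
    reference is the chi-square mixture with the LD eigenvalues as weights
    (direction is irrelevant to a sum of squares).
    """
    R = ld.R if isinstance(ld, LdMatrix) else np.atleast_2d(np.asarray(ld, float))
    p = clip_pvalues(pvals)
    if p.shape[0] != R.shape[0]:
        raise ValueError(f"{p.shape[0]} p-values but LD matrix of order {R.shape[0]}")
    z = np.minimum(stats.norm.isf(p / 2.0), Z_CAP)
    T = float(np.sum(z**2))
    lam = np.linalg.eigvalsh(R)
    lam = np.clip(lam, 0.0, None)
    return quadform_tail(T, lam)


def single_variant_gwas(dosages, variant_ids, chroms, positions, y, whiten=None):
    """Per-variant association scan producing a summary-statistics table.

    OLS of the (prepared) trait residual on each mean-imputed dosage, with
    an optional whitening matrix applied to both sides to absorb family
    structure. Returns a DataFrame with columns variant_id, chrom, pos,
    beta, se, p, maf.
    """
    D = np.atleast_2d(np.asarray(dosages, dtype=float))
    y = np.asarray(y, dtype=float)
    mafs = []
    Dimp = D.copy()
    for i in range(D.shape[0]):
        d = D[i]
        ok = ~np.isnan(d)
        f = d[ok].mean() / 2.0
        mafs.append(min(f, 1 - f))
        Dimp[i, ~ok] = d[ok].mean()
    if whiten is not None:
        yw = whiten @ y
        Dw = Dimp @ whiten.T
        ones = whiten @ np.ones(len(y))
    else:
        yw, Dw, ones = y, Dimp, np.ones(len(y))

    # project out the intercept once, then all slope tests are 1-D
    ones_n2 = float(ones @ ones)
    yr = yw - ones * (ones @ yw) / ones_n2
    n = len(y)
    Xr = Dw - np.outer(Dw @ ones / ones_n2, ones)
    sxx = np.einsum("ij,ij->i", Xr, Xr)
    sxy = Xr @ yr
    syy = float(yr @ yr)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        betas = sxy / sxx
        rss = np.maximum(syy - betas**2 * sxx, 0.0)
        ses = np.sqrt(rss / df / sxx)
        ps = 2 * stats.t.sf(np.abs(betas / ses), df)
    bad = ~np.isfinite(betas) | (sxx <= 0)
    betas[bad], ses[bad], ps[bad] = 0.0, np.inf, 1.0
    return pd.DataFrame(
        {
            "variant_id": list(variant_ids),
            "chrom": list(chroms),
            "pos": list(positions),
            "beta": betas,
            "se": ses,
            "p": clip_pvalues(ps),
            "maf": mafs,
        }
    )


def run_gwas_aggregation(
    summary: pd.DataFrame,
    genes: list[GeneModel],
    dosages_by_variant: dict[str, np.ndarray],
    trait: str,
    *,
    window: int = 50_000,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """PASCAL-style gene scores from a per-variant summary table.

    Variants with MAF >= ``maf_min`` are assigned to genes within
    ``window`` bp; LD within each gene is computed from the provided
    dosages; the sum-of-chi-squares statistic yields the gene p-value.
    Returns gene-score rows (source="GWAS").
    """
    s = summary.loc[summary["maf"] >= maf_min]
    triples = list(zip(s["variant_id"].astype(str), s["chrom"].astype(str), s["pos"]))
    assign = assign_snps_to_genes(triples, genes, window=window)
    pmap = dict(zip(s["variant_id"].astype(str), clip_pvalues(s["p"].to_numpy())))
    mafmap = dict(zip(s["variant_id"].astype(str), s["maf"]))

    rows = []
    for g in genes:
        vids = [v for v in assign.assignments.get(g.gene_id, []) if v in dosages_by_variant]
        if not vids:
            continue
        if len(vids) > MAX_VARIANTS_PER_GENE:
            vids = sorted(vids, key=lambda v: -mafmap[v])[:MAX_VARIANTS_PER_GENE]
            warnings.warn(f"{g.gene_id}: thinned to {MAX_VARIANTS_PER_GENE} variants by MAF")
        D = np.vstack([dosages_by_variant[v] for v in vids])
        ld = ld_correlation(D, vids)
        pv = np.array([pmap[v] for v in ld.variant_ids])
        rows.append(
            {
                "gene_id": g.gene_id,
                "trait": trait,
                "source": "GWAS",
                "category": "none",
                "p": gene_sum_test(pv, ld),
                "beta": np.nan,
                "n_units": len(ld.variant_ids),
            }
        )
    return pd.DataFrame(rows)
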