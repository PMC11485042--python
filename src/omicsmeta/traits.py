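"""Trait preparation: covariate residualization, stepwise genetic-PC
adjustment, rank-based inverse normal transform, and inflation diagnostics.

The empirical-null correction models a z-score vector as a mixture of a
dominant central (null) component and two signal components; the null
component's mean and standard deviation give the bias and inflation used to
rescale the scores. It is applied downstream only when the genomic
inflation factor exceeds 1.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "residualize",
    "stepwise_pc_adjust",
    "inverse_normal_transform",
    "genomic_inflation_factor",
    "EmpiricalNull",
    "empirical_null_correct",
    "prepare_trait",
]

#: Median of the 1-df chi-square distribution, the null reference for the GIF.
CHI2_1_MEDIAN = float(stats.chi2.median(1))  # 0.45493...


def residualize(y, X, *, add_intercept: bool = True):
    """Least-squares residuals of ``y`` on covariate matrix ``X``.

    Collinear columns are handled by the pseudoinverse (equivalent to
    dropping them); a warning is emitted when X is rank-deficient.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("covariate matrix is rank-deficient; collinear columns ignored")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def stepwise_pc_adjust(resid, pcs, alpha: float = 0.05):
    """Forward stepwise adjustment for principal components.

    PCs are visited in column order (PC1 first). A PC is retained iff its
    marginal association with the *current* residual has p < ``alpha``; the
    residual is then re-fit on the full retained set. Returns
    (residuals, retained_indices).
    """
    resid = np.asarray(resid, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim == 1:
        pcs = pcs[:, None]
    retained: list[int] = []
    current = resid
    for j in range(pcs.shape[1]):
        p = _marginal_pvalue(current, pcs[:, j])
        if p < alpha:
            retained.append(j)
            current = residualize(resid, pcs[:, retained])
    return current, retained


def _marginal_pvalue(y, x) -> float:
    """Two-sided p for the slope of a simple linear regression of y on x."""
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0 or n < 4:
        return 1.0
    beta = float(xc @ yc) / sxx
    rss = float(yc @ yc) - beta**2 * sxx
    df = n - 2
    if rss <= 0:
        return 0.0
    se = np.sqrt(rss / df / sxx)
    return 2 * float(stats.t.sf(abs(beta / se), df))


def inverse_normal_transform(values):
    """Rank-based inverse normal transform with the Blom offset.

    z_i = Phi^-1((r_i - 3/8) / (n + 1/4)), with average ranks for ties.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(v) == 0:
        raise ValueError("constant input: all values tied")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def genomic_inflation_factor(pvals) -> float:
    """GIF: median association chi-square over the null 1-df median.

    Each two-sided p is converted to a chi-square via Phi^-1(p/2)^2.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.norm.ppf(p / 2.0) ** 2
    return float(np.median(chi2) / CHI2_1_MEDIAN)


@dataclass
class EmpiricalNull:
    """Fitted empirical-null parameters: ``bias`` and ``inflation`` are the
    mean and sd of the dominant central mixture component."""

    bias: float
    inflation: float
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        if self.inflation <= 0:
            raise ValueError("inflation must be positive")


def empirical_null_correct(z, *, max_iter: int = 500, tol: float = 1e-8):
    """Estimate bias/inflation of a z-score vector and return corrected p.

    A 3-component normal mixture (one null component flanked by two signal
    components) is fitted by EM; the component closest to zero with the
    largest weight is taken as the null. Corrected z = (z - bias)/inflation;
    p-values are two-sided. Falls back to median/MAD if EM fails.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError("too few z-scores to fit an empirical null")

    scale0 = max(stats.median_abs_deviation(z, scale="normal"), 1e-3)
    med = float(np.median(z))
    means = np.array([med, med - 2.5 * scale0, med + 2.5 * scale0])
    sds = np.array([scale0, 2 * scale0, 2 * scale0])
    w = np.array([0.9, 0.05, 0.05])

    converged = False
    loglik_old = -np.inf
    for _ in range(max_iter):
        dens = np.array(
            [wk * stats.norm.pdf(z, mk, sk) for wk, mk, sk in zip(w, means, sds)]
        )
        total = dens.sum(axis=0)
        total = np.maximum(total, 1e-300)
        resp = dens / total
        loglik = float(np.sum(np.log(total)))
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        means = resp @ z / nk
        for k in range(3):
            var = float(resp[k] @ (z - means[k]) ** 2 / nk[k])
            sds[k] = np.sqrt(max(var, 1e-6))
        # identifiability constraint: the flanking signal components must
        # stay at least 2 null-sd away from the null mean, otherwise they
        # absorb the null's shoulders and shrink its fitted sd
        means[1] = min(means[1], means[0] - 2.0 * sds[0])
        means[2] = max(means[2], means[0] + 2.0 * sds[0])
        sds[1:] = np.maximum(sds[1:], 0.5 * sds[0])
        if abs(loglik - loglik_old) < tol * (1 + abs(loglik)):
            converged = True
            break
        loglik_old = loglik

    if converged:
        # component 0 is pinned to the centre by initialization and the
        # separation constraint, so it is the null component
        bias, inflation = float(means[0]), float(sds[0])
    else:
        warnings.warn("empirical-null EM did not converge; using median/MAD")
        bias = float(np.median(z))
        inflation = float(stats.median_abs_deviation(z, scale="normal"))
    inflation = max(inflation, 1e-6)

    null = EmpiricalNull(bias, inflation, w.copy(), means.copy(), sds.copy(), converged)
    z_corr = (z - bias) / inflation
    p_corr = 2 * stats.norm.sf(np.abs(z_corr))
    return null, np.clip(p_corr, 1e-300, 1.0)


def prepare_trait(y, covariates, pcs=None, *, alpha: float = 0.05):
    """Full trait preparation: covariate residualization, optional stepwise
    genetic-PC adjustment, then inverse normal transform.

    Returns (residuals, retained_pc_indices).
    """
    resid = residualize(np.asarray(y, float), covariates)
    retained: list[int] = []
    if pcs is not None:
        resid, retained = stepwise_pc_adjust(resid, pcs, alpha=alpha)
    return inverse_normal_transform(resid), retained
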