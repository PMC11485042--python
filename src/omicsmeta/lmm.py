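"""Family-relatedness variance model shared by the association stages.

One REML fit per trait of V = sigma_g^2 * 2K + sigma_e^2 * I (K the kinship
matrix, intercept-only mean model). Downstream per-gene tests whiten their
data with V^{-1/2}; with K = 0 the whitener is a scalar, so every such test
reduces exactly to its OLS form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["VarianceModel", "fit_variance_model"]


@dataclass
class VarianceModel:
    """Fitted V = sigma_g2 * 2K + sigma_e2 * I via its eigenbasis.

    ``U`` and ``d`` are the eigenvectors/eigenvalues of 2K; V's eigenvalues
    are ``sigma_g2 * d + sigma_e2``.
    """

    sigma_g2: float
    sigma_e2: float
    U: np.ndarray
    d: np.ndarray
    _p0: np.ndarray | None = None  # cached null projection

    @property
    def n(self) -> int:
        return len(self.d)

    def _v_eigs(self) -> np.ndarray:
        return self.sigma_g2 * self.d + self.sigma_e2

    def whiten(self, M):
        """Return V^{-1/2} @ M (M is a vector or an n x m matrix)."""
        v = self._v_eigs()
        M = np.asarray(M, dtype=float)
        return self.U @ ((self.U.T @ M).T / np.sqrt(v)).T

    def solve(self, M):
        """Return V^{-1} @ M."""
        v = self._v_eigs()
        M = np.asarray(M, dtype=float)
        return self.U @ ((self.U.T @ M).T / v).T

    def null_projection(self) -> np.ndarray:
        """P0 = V^-1 - V^-1 1 (1' V^-1 1)^-1 1' V^-1 (intercept removed).

        Cached: repeated variant-set tests against one trait reuse it.
        """
        if self._p0 is None:
            ones = np.ones(self.n)
            vi1 = self.solve(ones)
            self._p0 = self._vinv() - np.outer(vi1, vi1) / float(ones @ vi1)
        return self._p0

    def _vinv(self) -> np.ndarray:
        v = self._v_eigs()
        return (self.U / v) @ self.U.T


def fit_variance_model(y, K=None) -> VarianceModel:
    """REML fit of the polygenic variance model for one trait.

    ``K`` is the kinship matrix (expected relatedness; 2K is the additive
    genetic covariance). ``K=None`` or an all-zero matrix yields the
    independent-samples model with sigma_e2 equal to the usual unbiased
    variance estimate. Non-PSD K has negative eigenvalues clipped at zero
    with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K is None:
        K = np.zeros((n, n))
    A = 2.0 * np.asarray(K, dtype=float)
    A = 0.5 * (A + A.T)
    d, U = np.linalg.eigh(A)
    if d.min() < -1e-8 * max(1.0, d.max()):
        warnings.warn("kinship matrix not PSD; clipping negative eigenvalues")
    d = np.clip(d, 0.0, None)

    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def profile(gamma: float):
        """REML profile: gamma = sigma_g2 / sigma_e2."""
        w = 1.0 / (gamma * d + 1.0)
        sxx = float(w @ xt**2)
        beta = float(w @ (xt * yt)) / sxx
        r = yt - beta * xt
        s2 = float(w @ r**2) / (n - 1)
        ll = -0.5 * (
            np.sum(np.log(gamma * d + 1.0)) + (n - 1) * np.log(s2) + np.log(sxx)
        )
        return ll, s2

    if d.max() <= 0:
        _, s2 = profile(0.0)
        return VarianceModel(0.0, s2, U, d)

    res = optimize.minimize_scalar(
        lambda lg: -profile(np.exp(lg))[0],
        bounds=(np.log(1e-6), np.log(1e3)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    gamma = float(np.exp(res.x))
    ll_g, s2_g = profile(gamma)
    ll_0, s2_0 = profile(0.0)
    if ll_0 >= ll_g:  # boundary solution: no genetic variance
        return VarianceModel(0.0, s2_0, U, d)
    return VarianceModel(gamma * s2_g, s2_g, U, d)
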