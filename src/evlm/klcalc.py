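"""Kullback-Leibler divergences for Gaussian and nested linear models.

For two n-dimensional Gaussians f1 = N(mu1, S1), f2 = N(mu2, S2):

    K(f1, f2) = 0.5 [ tr(S2^{-1} S1) - n
                      + (mu2 - mu1)' S2^{-1} (mu2 - mu1)
                      + log(|S2| / |S1|) ].

For nested linear models sharing sigma^2 I (means X1 b1 and
X1 b1 + X2 b2) both directed divergences collapse to the same value
b2' X2'X2 b2 / (2 sigma^2), so the symmetric distance is 2K.  The
noncentrality of the comparison satisfies lam = 2K - design_load,
where the nonnegative design load measures how correlation between X2
and X1 dilutes the information the design carries about b2.

Natural logarithms throughout, consistent with the SIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ncfdist import lambda_formulation_A

__all__ = ["GaussianSpec", "KLResult", "kl_gaussian", "kl_nested_linear", "delta_k_hat"]


@dataclass(frozen=True)
class GaussianSpec:
    """Mean vector and covariance (full matrix or scalar sigma^2 * I)."""

    mean: np.ndarray
    cov: np.ndarray | float

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "mean", mean)
        if np.isscalar(self.cov) or np.ndim(self.cov) == 0:
            if float(self.cov) <= 0:
                raise ValueError("scalar covariance must be positive")
            object.__setattr__(self, "cov", float(self.cov))
        else:
            cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
            if cov.shape != (mean.size, mean.size):
                raise ValueError("covariance shape does not match the mean")
            # PD check via Cholesky
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise ValueError("covariance must be positive definite") from None
            object.__setattr__(self, "cov", cov)

    @property
    def dim(self) -> int:
        return self.mean.size

    def is_scalar_cov(self) -> bool:
        return isinstance(self.cov, float)


@dataclass(frozen=True)
class KLResult:
    K12: float
    K21: float

    @property
    def symmetric2K(self) -> float:
        return self.K12 + self.K21

    def to_dict(self) -> dict:
        return {"K12": self.K12, "K21": self.K21, "symmetric2K": self.symmetric2K}


def _kl_directed(fa: GaussianSpec, fb: GaussianSpec) -> float:
    """K(fa, fb) = E_fa[log fa - log fb]."""
    n = fa.dim
    d = fb.mean - fa.mean
    if fa.is_scalar_cov() and fb.is_scalar_cov():
        sa, sb = fa.cov, fb.cov
        return 0.5 * (n * sa / sb - n + float(d @ d) / sb + n * np.log(sb / sa))
    Sa = fa.cov * np.eye(n) if fa.is_scalar_cov() else fa.cov
    Sb = fb.cov * np.eye(n) if fb.is_scalar_cov() else fb.cov
    Lb = np.linalg.cholesky(Sb)
    Sb_inv_Sa = np.linalg.solve(Sb, Sa)
    quad = float(d @ np.linalg.solve(Sb, d))
    _, logdet_a = np.linalg.slogdet(Sa)
    logdet_b = 2.0 * float(np.sum(np.log(np.diag(Lb))))
    return 0.5 * (np.trace(Sb_inv_Sa) - n + quad + logdet_b - logdet_a)


def kl_gaussian(f1: GaussianSpec, f2: GaussianSpec) -> KLResult:
    """Both directed KL divergences between two multivariate normals."""
    if f1.dim != f2.dim:
        raise ValueError("dimension mismatch")
    return KLResult(K12=max(_kl_directed(f1, f2), 0.0),
                    K21=max(_kl_directed(f2, f1), 0.0))


def kl_nested_linear(X1, X2, beta2, sigma2: float) -> KLResult:
    """KL between nested linear models: b2' X2'X2 b2 / (2 sigma^2).

    Invariant to beta1 (the shared mean component cancels) and symmetric
    in this equal-covariance case, so K12 = K21.
    """
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    beta2 = np.atleast_1d(np.asarray(beta2, dtype=float))
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if X2.shape[1] != beta2.size:
        raise ValueError("beta2 length must match the number of X2 columns")
    v = X2 @ beta2
    K = float(v @ v) / (2.0 * sigma2)
    return KLResult(K12=K, K21=K)


def delta_k_hat(delta_sic: float, n: int) -> float:
    """Per-observation evidence Delta-K-hat = Delta-sic / n.

    Unlike raw Delta-sic values, Delta-K estimates are comparable across
    data sets of different sizes (given a common log base).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return delta_sic / n
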