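"""Noncentral F distribution utilities with an explicit parameter convention.

The noncentrality convention used throughout is the Poisson-mixture form:
the pdf is a mixture of (scaled) central F densities with Poisson weights
of mean ``lam / 2``.  Under this convention the distribution mean is

    E[F] = nu2 (nu1 + lam) / (nu1 (nu2 - 2)),   nu2 > 2.

Some software parameterizes the same family by ``xi = lam / 2``; the
:func:`convention_check` Monte Carlo guard distinguishes the two (e.g.,
at (nu1, nu2) = (1, 3) the mean is 9 with lam = 2 but 15 with lam = 4).

scipy.stats.ncf follows this convention and provides the cdf and
quantile; the pdf is computed here from the mixture series directly,
truncated when the accumulated Poisson weight exceeds 1 - 1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NoncentralFSpec",
    "LambdaDecomposition",
    "ConventionCheck",
    "ncf_pdf",
    "ncf_cdf",
    "ncf_quantile",
    "ncf_mean",
    "convention_check",
    "lambda_formulation_A",
    "lambda_formulation_B",
]

_POISSON_TAIL = 1e-12


@dataclass(frozen=True)
class NoncentralFSpec:
    """Degrees of freedom (nu1, nu2) and noncentrality lam >= 0."""

    nu1: int
    nu2: int
    lam: float

    def __post_init__(self):
        if self.nu1 < 1 or self.nu2 < 1:
            raise ValueError("degrees of freedom must be positive integers")
        if self.lam < 0:
            raise ValueError("noncentrality must be nonnegative")


def ncf_pdf(spec: NoncentralFSpec, u) -> np.ndarray | float:
    """Density of the noncentral F at u > 0 via the Poisson-mixture series.

    Each mixture component with Poisson index j is the density of
    ((nu1 + 2j)/nu1) * F(nu1 + 2j, nu2); the series is truncated once the
    neglected Poisson tail is below 1e-12.
    """
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any(u_arr <= 0):
        raise ValueError("density defined for u > 0 only")
    nu1, nu2, lam = spec.nu1, spec.nu2, spec.lam
    if lam == 0.0:
        out = stats.f.pdf(u_arr, nu1, nu2)
        return out if np.ndim(u) else float(out[0])
    half = lam / 2.0
    out = np.zeros_like(u_arr)
    cum = 0.0
    j = 0
    logw = -half  # log Poisson weight at j = 0
    while cum < 1.0 - _POISSON_TAIL:
        w = math.exp(logw)
        df1 = nu1 + 2 * j
        scale = nu1 / df1  # X = (df1/nu1) * F(df1, nu2)
        out += w * scale * stats.f.pdf(u_arr * scale, df1, nu2)
        cum += w
        j += 1
        logw += math.log(half) - math.log(j)
        if j > 100000:  # pragma: no cover - safety valve
            break
    return out if np.ndim(u) else float(out[0])


def _series_cdf(nu1: int, nu2: int, lam: float, u: np.ndarray) -> np.ndarray:
    """Poisson-mixture cdf, used where scipy's routine loses accuracy
    (very large noncentrality)."""
    half = lam / 2.0
    out = np.zeros_like(u)
    cum = 0.0
    j = max(int(half) - 200, 0)  # start near the dominant Poisson mass
    # walk outward from the mode in both directions
    js = sorted(range(max(j, 0), int(half) + 200 + 1),
                key=lambda t: abs(t - half))
    for jj in js:
        w = stats.poisson.pmf(jj, half)
        if w == 0.0 and cum > 0.5:
            continue
        df1 = nu1 + 2 * jj
        out += w * stats.f.cdf(u * nu1 / df1, df1, nu2)
        cum += w
        if cum >= 1.0 - _POISSON_TAIL:
            break
    return out


def ncf_cdf(spec: NoncentralFSpec, u) -> np.ndarray | float:
    """Cumulative distribution function at u (0 for u <= 0)."""
    u_arr = np.asarray(u, dtype=float)
    if spec.lam == 0.0:
        out = stats.f.cdf(u_arr, spec.nu1, spec.nu2)
    else:
        out = stats.ncf.cdf(u_arr, spec.nu1, spec.nu2, spec.lam)
        bad = ~np.isfinite(np.atleast_1d(out))
        if bad.any():
            fix = _series_cdf(
                spec.nu1, spec.nu2, spec.lam,
                np.atleast_1d(u_arr).astype(float)[bad],
            )
            out = np.atleast_1d(out)
            out[bad] = fix
            if np.ndim(u_arr) == 0:
                out = out[0]
    out = np.where(u_arr <= 0, 0.0, out)
    return out if np.ndim(u) else float(out)


def ncf_quantile(spec: NoncentralFSpec, p) -> np.ndarray | float:
    """Quantile function (generalized inverse of the cdf) for p in (0, 1)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("quantile probability must lie strictly in (0, 1)")
    if spec.lam == 0.0:
        out = stats.f.ppf(p_arr, spec.nu1, spec.nu2)
    else:
        out = stats.ncf.ppf(p_arr, spec.nu1, spec.nu2, spec.lam)
    return out if np.ndim(p) else float(out)


def ncf_mean(spec: NoncentralFSpec) -> float:
    """Closed-form mean nu2 (nu1 + lam) / (nu1 (nu2 - 2)); requires nu2 > 2."""
    if spec.nu2 <= 2:
        raise ValueError("mean does not exist for nu2 <= 2")
    return spec.nu2 * (spec.nu1 + spec.lam) / (spec.nu1 * (spec.nu2 - 2))


@dataclass(frozen=True)
class ConventionCheck:
    sample_mean: float
    expected_mean: float
    abs_error: float
    tolerance: float
    passed: bool
    n_draws: int
    seed: int


def convention_check(
    spec: NoncentralFSpec, n_draws: int = 1_000_000, seed: int = 0
) -> ConventionCheck:
    """Monte Carlo guard for the noncentrality convention.

    Draws F = (noncentral chi2(nu1, lam)/nu1) / (chi2(nu2)/nu2) and
    compares the sample mean with the closed-form mean.  The verdict
    tolerance is max(3 standard errors of the sample mean, 2% of the
    expected mean); the 2% floor covers nu2 <= 4 where the variance of
    the sampling distribution is infinite but the law of large numbers
    still applies slowly.
    """
    if spec.nu2 <= 2:
        raise ValueError("reference mean does not exist for nu2 <= 2")
    if n_draws < 10_000:
        raise ValueError("need at least 10,000 draws for a stable check")
    rng = np.random.default_rng(seed)
    if spec.lam == 0.0:
        num = rng.chisquare(spec.nu1, n_draws)
    else:
        num = rng.noncentral_chisquare(spec.nu1, spec.lam, n_draws)
    den = rng.chisquare(spec.nu2, n_draws)
    draws = (num / spec.nu1) / (den / spec.nu2)
    sample_mean = float(draws.mean())
    expected = ncf_mean(spec)
    se = float(draws.std(ddof=1)) / math.sqrt(n_draws)
    tol = max(3.0 * se, 0.02 * abs(expected))
    err = abs(sample_mean - expected)
    return ConventionCheck(
        sample_mean=sample_mean,
        expected_mean=expected,
        abs_error=err,
        tolerance=tol,
        passed=err <= tol,
        n_draws=n_draws,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# noncentrality from designs


@dataclass(frozen=True)
class LambdaDecomposition:
    """lam = 2K - design_load: how the design dilutes the KL signal.

    ``twoK`` is the symmetric KL distance between the two nested models;
    ``design_load`` is the nonnegative quadratic form subtracted from it,
    reflecting how non-orthogonality of X2 to X1 reduces the information
    the design carries about beta_2.
    """

    lam: float
    twoK: float
    design_load: float


def lambda_formulation_A(X1, X2, beta2, sigma2: float):
    """Noncentrality for the dropped-columns comparison (beta_2 = 0 null).

    lam = beta2' (X2'X2 - X2'X1 (X1'X1)^{-1} X1'X2) beta2 / sigma2.
    Returns ``(lam, LambdaDecomposition)``.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    beta2 = np.atleast_1d(np.asarray(beta2, dtype=float))
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if X1.shape[0] != X2.shape[0]:
        raise ValueError("X1 and X2 disagree on n")
    if X2.shape[1] != beta2.shape[0]:
        raise ValueError("beta2 length must match the number of X2 columns")
    sv = np.linalg.svd(X1, compute_uv=False)
    if sv[-1] <= 1e-10 * sv[0]:
        raise np.linalg.LinAlgError("X1'X1 is singular")
    X1tX1 = X1.T @ X1
    cross = X1.T @ X2
    A = X2.T @ X2 - cross.T @ np.linalg.solve(X1tX1, cross)
    lam = float(beta2 @ A @ beta2) / sigma2
    twoK = float(beta2 @ (X2.T @ X2) @ beta2) / sigma2
    lam = max(lam, 0.0)
    return lam, LambdaDecomposition(lam=lam, twoK=twoK, design_load=twoK - lam)


def lambda_formulation_B(X, L, h, beta, sigma2: float) -> float:
    """Noncentrality for the linear-constraint comparison L beta = h.

    lam = (L beta - h)' (L (X'X)^{-1} L')^{-1} (L beta - h) / sigma2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    L = np.atleast_2d(np.asarray(L, dtype=float))
    h = np.atleast_1d(np.asarray(h, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if np.linalg.matrix_rank(L) < L.shape[0]:
        raise np.linalg.LinAlgError("L is not full row rank")
    diff = L @ beta - h
    M = L @ np.linalg.solve(X.T @ X, L.T)
    return max(float(diff @ np.linalg.solve(M, diff)) / sigma2, 0.0)
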