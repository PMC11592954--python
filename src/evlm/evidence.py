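"""The Delta-SIC evidence function: design, thresholds, and post-data use.

Sign convention: Delta-SIC = SIC1 - SIC2, so positive values favor the
larger model (model 2) and negative values favor the nested model
(model 1).  For nested normal linear models,

    Delta-SIC = n log(1 + q F / (n - r)) - q log n,

a monotone transform of the F statistic, so pre-data probabilities of
misleading evidence (M1, M2), weak evidence (W1, W2) and strong correct
evidence (V1, V2) are tail areas of a noncentral F(q, n-r, lam).

Study design fixes a per-observation relative effect size delta (sigma
units) delimiting the "zone of indifference" around model 1; the design
boundary noncentrality is lam = n delta^2.  Thresholds k1 and k2 are set
from noncentral-F quantiles so that M2 <= gamma2 and M1 <= gamma1 at the
boundary.  Misleading-evidence probabilities for model 1 default to the
boundary lam rather than the literal null lam = 0: a departure smaller
than delta sigma is deemed consistent with model 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, stats

from .ncfdist import NoncentralFSpec, ncf_cdf, ncf_quantile

__all__ = [
    "EvidenceValue",
    "EvidenceDesign",
    "ErrorProbabilities",
    "EvidenceVerdict",
    "DegenerateDesignError",
    "SampleSizeNotAchievableError",
    "delta_sic_from_F",
    "f_from_delta_sic",
    "design_thresholds",
    "error_probabilities",
    "sample_size_for_threshold",
    "post_data_P",
    "delta_for_strong_evidence",
    "classify",
]


class DegenerateDesignError(ValueError):
    """The requested design has no inconclusive zone (psi1 >= psi2)."""


class SampleSizeNotAchievableError(ValueError):
    def __init__(self, msg, n_max=None, prob_at_n_max=None):
        super().__init__(msg)
        self.n_max = n_max
        self.prob_at_n_max = prob_at_n_max


@dataclass(frozen=True)
class EvidenceValue:
    delta_sic: float
    n: int
    r: int
    q: int
    F: float

    @property
    def delta_k_hat(self) -> float:
        return self.delta_sic / self.n

    def to_dict(self) -> dict:
        return {
            "delta_sic": self.delta_sic,
            "delta_k_hat": self.delta_k_hat,
            "n": self.n,
            "r": self.r,
            "q": self.q,
            "F": self.F,
        }


def _validate_shape(n: int, r: int, q: int) -> None:
    if not (n > r >= q >= 1):
        raise ValueError(f"need n > r >= q >= 1, got n={n}, r={r}, q={q}")


def delta_sic_from_F(F: float, n: int, r: int, q: int) -> EvidenceValue:
    """Delta-SIC = n log(1 + q F/(n-r)) - q log n for an observed F >= 0."""
    _validate_shape(n, r, q)
    if F < 0:
        raise ValueError("F must be nonnegative")
    ds = n * math.log1p(q * F / (n - r)) - q * math.log(n)
    return EvidenceValue(delta_sic=ds, n=n, r=r, q=q, F=F)


def f_from_delta_sic(k: float, n: int, r: int, q: int) -> float:
    """Invert the evidence transform: the F value mapping to Delta-SIC = k.

    Equals ((n-r)/q) (n^{q/n} e^{k/n} - 1); negative when k < -q log n,
    meaning no F >= 0 attains evidence that low.
    """
    _validate_shape(n, r, q)
    return (n - r) / q * (math.exp((k + q * math.log(n)) / n) - 1.0)


@dataclass(frozen=True)
class EvidenceDesign:
    """Pre-data design: boundary effect size, quantiles, and thresholds."""

    n: int
    r: int
    q: int
    delta: float
    gamma1: float
    gamma2: float
    lam: float
    psi1: float
    psi2: float
    k1: float
    k2: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r": self.r,
            "q": self.q,
            "delta": self.delta,
            "gamma1": self.gamma1,
            "gamma2": self.gamma2,
            "lam": self.lam,
            "psi1": self.psi1,
            "psi2": self.psi2,
            "k1": self.k1,
            "k2": self.k2,
        }


@dataclass(frozen=True)
class ErrorProbabilities:
    """Misleading (M), weak (W) and veridical (V) evidence probabilities.

    Index j refers to the model assumed to generate the data; M + W + V = 1.
    """

    M1: float
    M2: float
    W1: float
    W2: float
    V1: float
    V2: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("M1", "M2", "W1", "W2", "V1", "V2")}


def design_thresholds(
    n: int,
    r: int,
    q: int,
    delta: float,
    gamma1: float = 0.05,
    gamma2: float = 0.05,
) -> EvidenceDesign:
    """Set (k1, k2) so M2 <= gamma2 and M1 <= gamma1 at the boundary.

    psi1 and psi2 are the gamma2 and 1-gamma1 quantiles of the noncentral
    F(q, n-r, n delta^2); k_j is the evidence transform of psi_j.
    """
    _validate_shape(n, r, q)
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    for g in (gamma1, gamma2):
        if not 0.0 < g < 1.0:
            raise ValueError("gamma caps must lie in (0, 1)")
    lam = n * delta * delta
    spec = NoncentralFSpec(q, n - r, lam)
    psi1 = ncf_quantile(spec, gamma2)
    psi2 = ncf_quantile(spec, 1.0 - gamma1)
    if psi1 >= psi2:
        raise DegenerateDesignError(
            "gamma caps overlap (psi1 >= psi2): no inconclusive zone exists"
        )
    k1 = delta_sic_from_F(psi1, n, r, q).delta_sic
    k2 = delta_sic_from_F(psi2, n, r, q).delta_sic
    return EvidenceDesign(
        n=n, r=r, q=q, delta=delta, gamma1=gamma1, gamma2=gamma2,
        lam=lam, psi1=psi1, psi2=psi2, k1=k1, k2=k2,
    )


def error_probabilities(
    n: int, r: int, q: int, k1: float, k2: float, lam1: float, lam2: float
) -> ErrorProbabilities:
    """M/W/V probabilities for fixed thresholds under two scenarios.

    ``lam1`` is the noncentrality when model 1 is taken to generate the
    data (0 for the literal null, n delta^2 for the indifference-zone
    boundary); ``lam2`` when model 2 generates the data.  An evidence
    threshold below -q log n is unreachable by any F >= 0, and the
    probability below it is 0.
    """
    _validate_shape(n, r, q)
    if not k1 < k2:
        raise ValueError("need k1 < k2")
    u1 = f_from_delta_sic(k1, n, r, q)
    u2 = f_from_delta_sic(k2, n, r, q)
    s1 = NoncentralFSpec(q, n - r, lam1)
    s2 = NoncentralFSpec(q, n - r, lam2)
    below_k1_1 = ncf_cdf(s1, u1)
    below_k2_1 = ncf_cdf(s1, u2)
    below_k1_2 = ncf_cdf(s2, u1)
    below_k2_2 = ncf_cdf(s2, u2)
    M1 = 1.0 - below_k2_1
    V1 = below_k1_1
    W1 = below_k2_1 - below_k1_1
    M2 = below_k1_2
    V2 = 1.0 - below_k2_2
    W2 = below_k2_2 - below_k1_2
    return ErrorProbabilities(M1=M1, M2=M2, W1=W1, W2=W2, V1=V1, V2=V2)


def sample_size_for_threshold(
    k: float,
    which: str,
    gamma: float,
    delta: float,
    q: int,
    r_of_n: int | Callable[[int], int],
    n_max: int = 100_000,
    model1_lam: str = "boundary",
):
    """Sample size at which a predesignated threshold meets its error cap.

    With threshold ``k1`` fixed, the misleading probability
    M2(n) = P(Delta-SIC < k1 | boundary lam = n delta^2) is zero while k1
    is unreachable, rises to a hump, then decays; the returned n is the
    smallest integer past the final crossing, so the cap holds there and
    at every larger n.  With ``k2`` fixed and the default boundary
    scenario for model 1, M1(n) increases in n (the boundary evidence
    distribution drifts past k2), so the returned n is the largest
    integer meeting the cap; with ``model1_lam="null"`` (literal lam = 0)
    M1 decreases and the smallest compliant n is returned.  The
    continuous root of probability = gamma is reported alongside (n is
    discrete; the root-finding itself is continuous in n).
    """
    if which not in ("k1", "k2"):
        raise ValueError("which must be 'k1' or 'k2'")
    if model1_lam not in ("boundary", "null"):
        raise ValueError("model1_lam must be 'boundary' or 'null'")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    if delta <= 0:
        raise ValueError("delta must be positive for a solvable design")
    r_rule = (lambda n: r_of_n) if isinstance(r_of_n, int) else r_of_n

    def prob(x: float) -> float:
        """Misleading probability at (possibly non-integer) sample size x."""
        r = r_rule(int(math.ceil(x)))
        if x <= r or r < q:
            return 1.0
        # every piece (df2, lam, inverted-F point) is continuous in x, so
        # the continuous root is well defined between integers
        lam = x * delta * delta
        if which == "k2" and model1_lam == "null":
            lam = 0.0
        df2 = x - r
        u = (df2 / q) * (math.exp((k + q * math.log(x)) / x) - 1.0)
        if u <= 0:
            p_below = 0.0
        else:
            p_below = float(stats.ncf.cdf(u, q, df2, lam)) if lam > 0 else float(
                stats.f.cdf(u, q, df2)
            )
        return p_below if which == "k1" else 1.0 - p_below

    n_lo = next(n for n in range(2, n_max + 1) if n > r_rule(n))
    # locate the final crossing of gamma on a geometric grid
    grid = sorted(set(
        list(range(n_lo, min(n_lo + 64, n_max) + 1))
        + list(np.unique(np.geomspace(n_lo, n_max, 200).astype(int)))
    ))
    vals = [prob(float(x)) for x in grid]
    crossings = [
        i for i in range(len(grid) - 1)
        if (vals[i] - gamma) * (vals[i + 1] - gamma) < 0
    ]
    tol = 1e-9
    if not crossings:
        if all(v <= gamma + tol for v in vals):
            return {
                "n": n_lo,
                "continuous_root": float(n_lo),
                "probability_at_n": prob(n_lo),
                "which": which,
                "gamma": gamma,
                "k": k,
                "note": "misleading probability never exceeds gamma",
            }
        raise SampleSizeNotAchievableError(
            f"no n <= {n_max} attains the bound; probability at n_max is "
            f"{vals[-1]:.4g}",
            n_max=n_max,
            prob_at_n_max=vals[-1],
        )
    i = crossings[-1]
    root = optimize.brentq(
        lambda z: prob(z) - gamma, grid[i], grid[i + 1], xtol=1e-8
    )
    decreasing = vals[i] > vals[i + 1]
    if decreasing:
        n_star = max(n_lo, int(math.floor(root)))
        while prob(n_star) > gamma + tol:
            n_star += 1
    else:
        n_star = int(math.ceil(root))
        while n_star > n_lo and prob(n_star) > gamma + tol:
            n_star -= 1
        if prob(n_star) > gamma + tol:
            raise SampleSizeNotAchievableError(
                "cap cannot be met at any admissible n", n_max=n_max,
                prob_at_n_max=vals[-1],
            )
    return {
        "n": n_star,
        "continuous_root": float(root),
        "probability_at_n": prob(n_star),
        "which": which,
        "gamma": gamma,
        "k": k,
        "crossing": "decreasing" if decreasing else "increasing",
    }


def post_data_P(
    delta_sic_obs: float, n: int, r: int, q: int, delta: float
) -> tuple[float, float]:
    """Post-data extremeness probabilities (P1, P2) at boundary effect delta.

    P2 is the largest probability, under model 2 at the indifference-zone
    boundary lam = n delta^2, of evidence at least as favorable to
    model 1 as observed; P1 = 1 - P2 is the analogue under model 1.
    """
    _validate_shape(n, r, q)
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    u = f_from_delta_sic(delta_sic_obs, n, r, q)
    spec = NoncentralFSpec(q, n - r, n * delta * delta)
    P2 = ncf_cdf(spec, u)
    return 1.0 - P2, P2


def delta_for_strong_evidence(
    delta_sic_obs: float,
    n: int,
    r: int,
    q: int,
    target_p: float = 0.05,
    delta_max: float = 10.0,
):
    """Boundary delta at which P2(delta) equals target_p.

    P2 is strictly decreasing in delta (raising lam = n delta^2 shifts
    the noncentral F right, shrinking the area below the fixed observed
    point), so the smallest effect size for which the observed evidence
    counts as strong (P2 <= target_p) is the unique root of
    P2(delta) = target_p, found by monotone bracketing.  When no root
    exists below ``delta_max`` a boundary report (dict with
    ``root=None`` and the attained range) is returned instead of raising.
    """
    if not 0.0 < target_p < 1.0:
        raise ValueError("target_p must lie in (0, 1)")

    def g(d: float) -> float:
        return post_data_P(delta_sic_obs, n, r, q, d)[1] - target_p

    lo, hi = 0.0, delta_max
    if g(lo) < 0 or g(hi) > 0:
        return {
            "root": None,
            "P2_at_0": g(lo) + target_p,
            "P2_at_delta_max": g(hi) + target_p,
            "delta_max": delta_max,
        }
    root = optimize.brentq(g, lo, hi, xtol=1e-10)
    return {"root": float(root), "target_p": target_p}


@dataclass(frozen=True)
class EvidenceVerdict:
    category: str  # strong_model1 | inconclusive | strong_model2
    delta_sic: float
    P1: float
    P2: float
    delta_boundary: float

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "delta_sic": self.delta_sic,
            "P1": self.P1,
            "P2": self.P2,
            "delta_boundary": self.delta_boundary,
        }


def classify(delta_sic_obs: float, design: EvidenceDesign) -> EvidenceVerdict:
    """Trichotomous verdict for an observed evidence value.

    Boundary ties (delta_sic equal to k1 or k2) are classified as
    inconclusive: a conservative convention for a measure-zero event.
    """
    if not design.k1 < design.k2:
        raise ValueError("design thresholds must satisfy k1 < k2")
    if delta_sic_obs < design.k1:
        category = "strong_model1"
    elif delta_sic_obs > design.k2:
        category = "strong_model2"
    else:
        category = "inconclusive"
    P1, P2 = post_data_P(
        delta_sic_obs, design.n, design.r, design.q, design.delta
    )
    return EvidenceVerdict(
        category=category,
        delta_sic=delta_sic_obs,
        P1=P1,
        P2=P2,
        delta_boundary=design.delta,
    )
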