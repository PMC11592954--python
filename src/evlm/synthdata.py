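"""Synthetic data generators and the packaged citrus-yield fixture.

Factorial data are generated from the normal linear model
y ~ N(X beta, sigma^2 I).  The interaction coefficient vector is a fixed
alternating +-1 reference pattern rescaled so that the noncentrality of
the interaction-vs-main-effects comparison equals exactly n delta^2 for
the requested per-observation relative effect size delta; the generator
therefore realizes the boundary of the design's zone of indifference.

The citrus fixture is a balanced two-way layout: fruit yields of 24
trees, 3 varieties x 4 pesticides, 2 trees per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .linmod import DesignMatrix, ModelData, build_design
from .ncfdist import lambda_formulation_A

__all__ = ["FactorialSpec", "SyntheticFactorial", "generate_factorial",
           "citrus", "generate_regression"]


# Table of citrus yields: (variety, pesticide) -> two replicate trees.
_CITRUS = {
    (1, 1): (49, 39), (1, 2): (50, 55), (1, 3): (43, 38), (1, 4): (53, 48),
    (2, 1): (55, 41), (2, 2): (67, 58), (2, 3): (53, 42), (2, 4): (85, 73),
    (3, 1): (66, 68), (3, 2): (85, 92), (3, 3): (69, 62), (3, 4): (85, 99),
}


def citrus() -> ModelData:
    """The 24 citrus-tree fruit yields (3 varieties x 4 pesticides x 2)."""
    rows = []
    for (tree, pest), ys in _CITRUS.items():
        for y in ys:
            rows.append((float(y), str(tree), str(pest)))
    df = pd.DataFrame(rows, columns=["yield", "tree", "pest"])
    return ModelData(
        y=df["yield"].to_numpy(),
        predictors=df[["tree", "pest"]],
        factors=frozenset({"tree", "pest"}),
    )


@dataclass(frozen=True)
class FactorialSpec:
    """Balanced factorial generating model at a target interaction size.

    ``interaction_scale`` is the per-observation relative effect size
    delta of the interaction comparison in residual-sigma units; the
    realized noncentrality is exactly n * delta^2.
    """

    levels: tuple[int, int] = (3, 4)
    cell_size: int = 2
    mu: float = 0.0
    main_effects: tuple[tuple[float, ...], ...] | None = None
    interaction_scale: float = 0.5
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.levels) != 2 or any(l < 2 for l in self.levels):
            raise ValueError("need two factors with at least 2 levels each")
        if self.cell_size < 1:
            raise ValueError("cell_size must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.interaction_scale < 0:
            raise ValueError("interaction_scale must be nonnegative")
        if self.main_effects is not None:
            for lv, eff in zip(self.levels, self.main_effects):
                if len(eff) != lv:
                    raise ValueError("effect vector length must match levels")
                if abs(sum(eff)) > 1e-8:
                    raise ValueError("effect vectors must sum to zero")

    @property
    def n(self) -> int:
        return self.levels[0] * self.levels[1] * self.cell_size


@dataclass(frozen=True)
class SyntheticFactorial:
    """Generated data plus the ground truth used to make it."""

    data: ModelData
    design_full: DesignMatrix
    X1: np.ndarray
    X2: np.ndarray
    beta2: np.ndarray
    mean: np.ndarray
    sigma: float
    lam: float
    dropped_columns: tuple[str, ...]


def _interaction_pattern(q: int) -> np.ndarray:
    """Alternating +-1 reference direction in interaction-coefficient space."""
    return np.array([1.0 if j % 2 == 0 else -1.0 for j in range(q)])


def generate_factorial(spec: FactorialSpec) -> SyntheticFactorial:
    """Draw one balanced factorial data set at the delta boundary.

    The additive surface is mu + a_i + b_j (treatment-coded internally);
    the interaction term X2 beta2 uses the alternating reference pattern
    scaled so the interaction-comparison noncentrality equals n delta^2.
    """
    l1, l2 = spec.levels
    m = spec.cell_size
    n = spec.n
    f1 = np.repeat([str(i + 1) for i in range(l1)], l2 * m)
    f2 = np.tile(np.repeat([str(j + 1) for j in range(l2)], m), l1)
    preds = pd.DataFrame({"f1": f1, "f2": f2})
    base = ModelData(y=np.zeros(n), predictors=preds,
                     factors=frozenset({"f1", "f2"}))
    design = build_design(base, ["1", "f1", "f2", "f1:f2"])
    inter_cols = tuple(c for c in design.column_names if ":" in c)
    main = design.drop(inter_cols)
    X1 = main.matrix
    X2 = design.matrix[:, [design.column_names.index(c) for c in inter_cols]]

    # additive mean surface
    a = np.zeros(l1) if spec.main_effects is None else np.asarray(spec.main_effects[0])
    b = np.zeros(l2) if spec.main_effects is None else np.asarray(spec.main_effects[1])
    ai = a[f1.astype(int) - 1]
    bj = b[f2.astype(int) - 1]
    mean = spec.mu + ai + bj

    q = X2.shape[1]
    delta = spec.interaction_scale
    if delta > 0:
        pattern = _interaction_pattern(q)
        lam_unit, _ = lambda_formulation_A(X1, X2, pattern, spec.sigma**2)
        if lam_unit <= 0:
            raise ValueError("interaction pattern carries no signal; "
                             "cannot realize a positive delta")
        c = np.sqrt(n * delta**2 / lam_unit)
        beta2 = c * pattern
        mean = mean + X2 @ beta2
        lam = float(n * delta**2)
    else:
        beta2 = np.zeros(q)
        lam = 0.0

    rng = np.random.default_rng(spec.seed)
    y = mean + spec.sigma * rng.standard_normal(n)
    data = ModelData(y=y, predictors=preds, factors=frozenset({"f1", "f2"}))
    return SyntheticFactorial(
        data=data, design_full=design, X1=X1, X2=X2, beta2=beta2,
        mean=mean, sigma=spec.sigma, lam=lam, dropped_columns=inter_cols,
    )


def generate_regression(
    n: int,
    coefficients: Sequence[float],
    sigma: float,
    designed: bool = True,
    seed: int = 0,
) -> ModelData:
    """Regression data with quantitative predictors and normal noise.

    ``coefficients[0]`` is the intercept.  Designed predictors are fixed
    low-discrepancy grids (van der Corput sequences in bases 2, 3, 5, ...
    scaled to [-1, 1]), identical for every seed; undesigned predictors
    are standard-normal draws.  Only the noise (and undesigned
    predictors) consume the seed.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    p = coefficients.size - 1
    if n <= coefficients.size:
        raise ValueError("need n greater than the number of coefficients")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    if designed:
        primes = [2, 3, 5, 7, 11, 13, 17, 19]
        if p > len(primes):
            raise ValueError("too many designed predictors")
        cols = [2.0 * _van_der_corput(n, primes[j]) - 1.0 for j in range(p)]
    else:
        cols = [rng.standard_normal(n) for _ in range(p)]
    preds = pd.DataFrame({f"x{j + 1}": c for j, c in enumerate(cols)})
    X = np.column_stack([np.ones(n)] + cols)
    y = X @ coefficients + sigma * rng.standard_normal(n)
    return ModelData(y=y, predictors=preds)


def _van_der_corput(n: int, base: int) -> np.ndarray:
    out = np.zeros(n)
    for i in range(n):
        x, denom, k = 0.0, 1.0, i + 1
        while k:
            k, rem = divmod(k, base)
            denom *= base
            x += rem / denom
        out[i] = x
    return out
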