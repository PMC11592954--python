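"""Bootstrap estimation of the evidence-function distribution.

Three resampling schemes for the nested-model Delta-SIC:

* ``parametric``: responses redrawn from N(X beta_hat, sigma2_unbiased I)
  of a chosen generating model (the unbiased variance estimate is used
  for generation; the ML estimate would understate the noise at small
  n - r);
* ``residual_semiparametric``: fitted values plus residuals resampled
  with replacement (conditional-on-X, "local" inference);
* ``stratified_balanced``: within-cell resampling of median-centered,
  variance-inflated residuals, balanced so that each residual is used
  exactly B times across the B replicates.

Every replicate refits both models of the nested pair (responses only
are resampled; design matrices are fixed) and records Delta-sic*.  The
refits are computed for all B replicates at once through orthonormal
bases of the two design column spaces: SSE = ||y||^2 - ||Q'y||^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .linmod import DesignMatrix, LinearModelFit, ModelData, build_design, fit
from .ncfdist import lambda_formulation_A

__all__ = [
    "ModelPair",
    "BootstrapConfig",
    "BootstrapDistribution",
    "BootstrapSummary",
    "StratificationError",
    "parametric_bootstrap",
    "residual_semiparametric_bootstrap",
    "stratified_balanced_bootstrap",
    "summarize",
    "apparent_reliability",
    "sample_size_curve",
    "interaction_summary",
]


class StratificationError(ValueError):
    """A cell is too small for within-cell resampling."""


@dataclass(frozen=True)
class ModelPair:
    """A nested comparison: full design and the columns dropped in model 1."""

    design_full: DesignMatrix
    dropped_columns: tuple

    def __post_init__(self):
        object.__setattr__(self, "dropped_columns", tuple(self.dropped_columns))
        idx = self.design_full.column_indices(self.dropped_columns)
        if len(idx) == self.design_full.r:
            raise ValueError("model pair would drop every column")

    @property
    def q(self) -> int:
        return len(self.dropped_columns)

    @property
    def r(self) -> int:
        return self.design_full.r

    @property
    def n(self) -> int:
        return self.design_full.n


def _orth(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return q


def delta_sic_many(pair: ModelPair, Y: np.ndarray) -> np.ndarray:
    """Delta-sic* for each row of Y (B x n), both models refit per row."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, r, q = pair.n, pair.r, pair.q
    X2 = pair.design_full.matrix
    X1 = pair.design_full.drop(pair.dropped_columns).matrix
    Q2, Q1 = _orth(X2), _orth(X1)
    tot = np.einsum("bi,bi->b", Y, Y)
    sse2 = tot - np.einsum("bi,bi->b", Y @ Q2, Y @ Q2)
    sse1 = tot - np.einsum("bi,bi->b", Y @ Q1, Y @ Q1)
    # snap round-off-level sums of squares to zero (cf. linmod.fit)
    sse2 = np.where(sse2 <= 1e-24 * tot, 0.0, sse2)
    sse1 = np.where(sse1 <= 1e-24 * tot, 0.0, sse1)
    sse2 = np.maximum(sse2, 0.0)
    sse1 = np.maximum(sse1, sse2)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(sse2 > 0, (sse1 - sse2) / q / (sse2 / (n - r)), np.inf)
        out = n * np.log1p(q * F / (n - r)) - q * math.log(n)
        # y in the span of X1: likelihood ratio 1, so F = 0 exactly
        out = np.where((sse2 == 0) & (sse1 == sse2), -q * math.log(n), out)
    return out


@dataclass(frozen=True)
class BootstrapConfig:
    model_pair: ModelPair
    B: int = 1024
    seed: int = 0
    scaling: str = "sqrt"  # residual inflation in the stratified scheme

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.scaling not in ("sqrt", "literal"):
            raise ValueError("scaling must be 'sqrt' or 'literal'")

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "scaling": self.scaling,
            "dropped_columns": [str(c) for c in self.model_pair.dropped_columns],
        }


def apparent_reliability(values: np.ndarray, identified_sign: float | None = None) -> float:
    """Fraction of bootstrap evidence values on the identified model's side.

    By default the identified model is the one favored by the bootstrap
    distribution itself (the sign of its mean); pass ``identified_sign``
    (e.g., the sign of the observed Delta-sic) to override.
    """
    values = np.asarray(values, dtype=float)
    if identified_sign is None:
        identified_sign = np.sign(np.mean(values))
    if identified_sign == 0:
        return 0.5
    return float(np.mean(np.sign(values) == np.sign(identified_sign)))


@dataclass(frozen=True)
class BootstrapDistribution:
    """B resampled Delta-sic* values with EDF summaries."""

    values: np.ndarray
    n: int
    observed_delta_sic: float
    method: str
    config: BootstrapConfig

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def quantiles(self, probs: Sequence[float]) -> dict[float, float]:
        qs = np.quantile(self.values, list(probs))
        return {float(p): float(v) for p, v in zip(probs, qs)}

    @property
    def aR(self) -> float:
        return apparent_reliability(self.values)

    @property
    def delta_k_values(self) -> np.ndarray:
        return self.values / self.n

    def edf(self) -> pd.DataFrame:
        """Two-column empirical distribution function (value, ecdf)."""
        v = np.sort(self.values)
        return pd.DataFrame(
            {"delta_sic": v, "ecdf": np.arange(1, len(v) + 1) / len(v)}
        )


def _finish(values, pair, y_obs, method, config) -> BootstrapDistribution:
    obs = float(delta_sic_many(pair, y_obs[None, :])[0])
    return BootstrapDistribution(
        values=np.asarray(values, dtype=float),
        n=pair.n,
        observed_delta_sic=obs,
        method=method,
        config=config,
    )


def parametric_bootstrap(
    generating_fit: LinearModelFit, config: BootstrapConfig
) -> BootstrapDistribution:
    """Redraw responses from N(X beta_hat, sigma2_unbiased I) and refit."""
    pair = config.model_pair
    n = pair.n
    if generating_fit.n != n:
        raise ValueError("generating fit and model pair disagree on n")
    sigma2 = generating_fit.sigma2_unbiased
    rng = np.random.default_rng(config.seed)
    Y = generating_fit.fitted[None, :] + math.sqrt(sigma2) * rng.standard_normal(
        (config.B, n)
    )
    values = delta_sic_many(pair, Y)
    y_obs = generating_fit.fitted + generating_fit.residuals
    return _finish(values, pair, y_obs, "parametric", config)


def residual_semiparametric_bootstrap(
    generating_fit: LinearModelFit, config: BootstrapConfig
) -> BootstrapDistribution:
    """Resample fitted-model residuals with replacement (conditional on X)."""
    pair = config.model_pair
    n = pair.n
    if generating_fit.n != n:
        raise ValueError("generating fit and model pair disagree on n")
    if generating_fit.n <= generating_fit.r:
        raise ValueError("saturated fit leaves no residual variation")
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n, size=(config.B, n))
    Y = generating_fit.fitted[None, :] + generating_fit.residuals[idx]
    values = delta_sic_many(pair, Y)
    y_obs = generating_fit.fitted + generating_fit.residuals
    return _finish(values, pair, y_obs, "residual_semiparametric", config)


def stratified_balanced_bootstrap(
    data: ModelData,
    factors: Sequence[str],
    config: BootstrapConfig,
    return_responses: bool = False,
):
    """Within-cell balanced resampling of inflated, median-centered residuals.

    Per cell i: residuals are y_ij minus the cell median, multiplied by
    s_i = sqrt(n_i/(n_i - 1)) (default) so their expected sample variance
    matches the cell population variance; the literal factor
    n_i/(n_i - 1) is available via ``config.scaling = "literal"``.
    Balance is realized by concatenating B copies of each cell's residual
    pool, permuting within cell, and slicing into B replicates, so each
    residual occurs exactly B times over the whole set.
    """
    pair = config.model_pair
    n = data.n
    if pair.n != n:
        raise ValueError("data and model pair disagree on n")
    B = config.B
    rng = np.random.default_rng(config.seed)
    Y = np.empty((B, n))
    groups = data.predictors.groupby(list(factors), sort=True, observed=True)
    for key, sub in groups.indices.items():
        idx = np.asarray(sub)
        ni = idx.size
        if ni < 2:
            raise StratificationError(
                f"cell {key!r} has a single observation; cannot stratify"
            )
        med = float(np.median(data.y[idx]))
        s = math.sqrt(ni / (ni - 1)) if config.scaling == "sqrt" else ni / (ni - 1)
        res = (data.y[idx] - med) * s
        pool = np.tile(res, B)
        rng.shuffle(pool)
        Y[:, idx] = med + pool.reshape(B, ni)
    values = delta_sic_many(pair, Y)
    dist = _finish(values, pair, data.y, "stratified_balanced", config)
    return (dist, Y) if return_responses else dist


@dataclass(frozen=True)
class BootstrapSummary:
    method: str
    B: int
    seed: int
    mean: float
    median: float
    quantiles: dict
    aR: float
    observed_delta_sic: float
    ci_delta_sic: tuple[float, float]
    ci_delta_k: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "B": self.B,
            "seed": self.seed,
            "mean": self.mean,
            "median": self.median,
            "quantiles": {str(k): v for k, v in self.quantiles.items()},
            "aR": self.aR,
            "observed_delta_sic": self.observed_delta_sic,
            "ci_delta_sic": list(self.ci_delta_sic),
            "ci_delta_k": list(self.ci_delta_k),
        }


def summarize(
    dist: BootstrapDistribution,
    probs: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
    ci_level: float = 0.90,
) -> BootstrapSummary:
    """Percentile-method summary of a bootstrap distribution.

    The Delta-K interval is the Delta-SIC interval divided by n.
    """
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(dist.values, [alpha, 1.0 - alpha])
    return BootstrapSummary(
        method=dist.method,
        B=dist.config.B,
        seed=dist.config.seed,
        mean=dist.mean,
        median=dist.median,
        quantiles=dist.quantiles(probs),
        aR=dist.aR,
        observed_delta_sic=dist.observed_delta_sic,
        ci_delta_sic=(float(lo), float(hi)),
        ci_delta_k=(float(lo) / dist.n, float(hi) / dist.n),
    )


# ---------------------------------------------------------------------------
# sample-size simulation (effect of adding replicates per cell)


def _expanded_factorial(data: ModelData, factors: Sequence[str], cell_size: int):
    """Balanced factor frame with ``cell_size`` replicates per cell."""
    levels = [data.levels(f) for f in factors]
    rows = []
    for a in levels[0]:
        for b in levels[1]:
            rows.extend([(a, b)] * cell_size)
    return pd.DataFrame(rows, columns=list(factors))


def sample_size_curve(
    data: ModelData,
    factors: Sequence[str],
    cell_sizes: Sequence[int],
    B: int = 200,
    n_outer: int = 100,
    seed: int = 0,
    probs: Sequence[float] = (0.05, 0.5, 0.95),
) -> pd.DataFrame:
    """Averaged bootstrap confidence points for Delta-K versus cell size.

    The generating model is the full interaction model fitted to ``data``
    (mean = fitted cell means, variance = sigma2_unbiased).  For each
    cell size, ``n_outer`` data sets are simulated; each is bootstrapped
    (parametric and stratified, B replicates) and the requested
    confidence points of Delta-K-hat = Delta-sic*/n are averaged over the
    outer simulations.  The returned frame also carries the pseudo-true
    per-observation Delta-K of the generating model (its noncentrality
    divided by n, the large-n limit of the estimand).
    """
    if min(cell_sizes) < 2:
        raise ValueError("stratified resampling needs cell sizes >= 2")
    terms = ["1", factors[0], factors[1], f"{factors[0]}:{factors[1]}"]
    design = build_design(data, terms)
    inter = tuple(c for c in design.column_names if ":" in c)
    full_fit = fit(data, design)
    sigma2 = full_fit.sigma2_unbiased
    # pseudo-true per-observation noncentrality of the generating model
    X1 = design.drop(inter).matrix
    X2 = design.matrix[:, design.column_indices(inter)]
    beta2 = full_fit.beta_hat[design.column_indices(inter)]
    lam_gen, _ = lambda_formulation_A(X1, X2, beta2, sigma2)
    pseudo_true = lam_gen / data.n

    # cell means of the generating (full) model
    cell_mean = {}
    for key, idx in data.predictors.groupby(list(factors), observed=True).indices.items():
        cell_mean[key] = float(np.mean(full_fit.fitted[np.asarray(idx)]))

    root = np.random.default_rng(seed)
    records = []
    for m in cell_sizes:
        frame = _expanded_factorial(data, factors, m)
        mean_vec = np.array([cell_mean[tuple(rw)] for rw in frame.itertuples(index=False)])
        n_m = len(frame)
        template = ModelData(y=np.zeros(n_m), predictors=frame,
                             factors=frozenset(factors))
        design_m = build_design(template, terms)
        pair_m = ModelPair(design_m, tuple(c for c in design_m.column_names if ":" in c))
        acc = {("parametric", p): 0.0 for p in probs}
        acc.update({("stratified", p): 0.0 for p in probs})
        for _ in range(n_outer):
            y_sim = mean_vec + math.sqrt(sigma2) * root.standard_normal(n_m)
            sim = ModelData(y=y_sim, predictors=frame, factors=frozenset(factors))
            cfg = BootstrapConfig(model_pair=pair_m, B=B,
                                  seed=int(root.integers(2**31 - 1)))
            gen_fit = fit(sim, design_m)
            par = parametric_bootstrap(gen_fit, cfg)
            strat = stratified_balanced_bootstrap(sim, factors, cfg)
            for p, v in par.quantiles(probs).items():
                acc[("parametric", p)] += v / n_m
            for p, v in strat.quantiles(probs).items():
                acc[("stratified", p)] += v / n_m
        for method in ("parametric", "stratified"):
            rec = {"cell_size": m, "n": n_m, "method": method,
                   "pseudo_true_delta_k": pseudo_true}
            for p in probs:
                rec[f"q{p:g}"] = acc[(method, p)] / n_outer
            records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# interaction profiles


def interaction_summary(
    data: ModelData,
    factors: tuple[str, str],
    level_ci: float = 0.95,
) -> dict:
    """Cell means with pooled-SE confidence intervals and slope bounds.

    The pooled standard error uses the full-model error mean square, so
    every cell interval has half-width t_{1-(1-level)/2, n-r} *
    sqrt(MSE/n_i).  For each profile (level of the first factor) and each
    adjacent pair of second-factor levels, the extreme plausible slopes
    run corner-to-corner between the interval endpoints; the slope
    confidence level is level_ci squared.
    """
    fa, fb = factors
    terms = ["1", fa, fb, f"{fa}:{fb}"]
    design = build_design(data, terms)
    full = fit(data, design)
    mse = full.sigma2_unbiased
    dof = data.n - design.r
    tcrit = float(stats.t.ppf(0.5 + level_ci / 2.0, dof))
    cells = []
    groups = data.predictors.groupby([fa, fb], sort=True, observed=True).indices
    means = {}
    for key, idx in groups.items():
        idx = np.asarray(idx)
        if idx.size < 1:
            raise ValueError(f"missing cell {key!r}")
        m = float(np.mean(data.y[idx]))
        half = tcrit * math.sqrt(mse / idx.size)
        means[key] = (m, m - half, m + half, idx.size)
        cells.append({fa: key[0], fb: key[1], "mean": m,
                      "lower": m - half, "upper": m + half, "n_cell": idx.size})
    la, lb = data.levels(fa), data.levels(fb)
    for a in la:
        for b in lb:
            if (a, b) not in means:
                raise ValueError(f"missing cell {(a, b)!r}")
    slopes = []
    for a in la:
        for j in range(len(lb) - 1):
            m1, lo1, hi1, _ = means[(a, lb[j])]
            m2, lo2, hi2, _ = means[(a, lb[j + 1])]
            slopes.append({
                fa: a, "segment": f"{lb[j]}->{lb[j + 1]}",
                "slope": m2 - m1,
                "min_slope": lo2 - hi1,
                "max_slope": hi2 - lo1,
            })
    return {
        "cells": pd.DataFrame(cells),
        "slopes": pd.DataFrame(slopes),
        "level_ci": level_ci,
        "slope_level": level_ci**2,
        "mse": mse,
        "df_error": dof,
    }
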