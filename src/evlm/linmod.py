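"""Normal linear fixed-effects models and nested-model comparisons.

The model is y ~ N(X beta, sigma^2 I) with a full-column-rank design
matrix X (n x r).  Two nested models are compared through the classical
F statistic, the generalized likelihood ratio G^2 = n log(1 + q F/(n-r)),
and (in :mod:`evlm.evidence`) the Schwarz-penalized evidence function
Delta-SIC = G^2 - q log n.

Two equivalent nested-model formulations are supported:

* Formulation A drops a set of design-matrix columns (beta_2 = 0);
* Formulation B imposes q linear constraints L beta = h.

All logarithms are natural; this matters because Delta-SIC / n estimates
a Kullback-Leibler difference that is only comparable across studies
when a common log base is used.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelData",
    "DesignMatrix",
    "LinearModelFit",
    "NestedComparison",
    "ContrastSpec",
    "RankDeficientError",
    "DegenerateFitError",
    "read_csv",
    "build_design",
    "fit",
    "compare_nested_A",
    "compare_nested_B",
    "anova_table",
]

# Relative tolerance (vs. the largest singular value) for declaring a
# design matrix rank deficient.
RANK_RTOL = 1e-8


class RankDeficientError(ValueError):
    """Design (or constraint) matrix does not have full rank."""


class DegenerateFitError(ValueError):
    """A quantity is undefined because the fit is saturated (n == r)."""


@dataclass(frozen=True)
class ModelData:
    """Response vector plus a table of named predictor columns.

    Categorical predictors are columns with non-numeric dtype (or numeric
    columns explicitly listed in ``factors``); everything else is treated
    as quantitative.
    """

    y: np.ndarray
    predictors: pd.DataFrame
    factors: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if y.ndim != 1:
            raise ValueError("response must be one-dimensional")
        if len(y) != len(self.predictors):
            raise ValueError("response and predictors disagree on n")
        if len(y) < 2:
            raise ValueError("need at least 2 observations")
        if np.isnan(y).any() or self.predictors.isna().any().any():
            raise ValueError("missing values are not supported")

    @property
    def n(self) -> int:
        return len(self.y)

    def is_factor(self, name: str) -> bool:
        if name in self.factors:
            return True
        return not pd.api.types.is_numeric_dtype(self.predictors[name])

    def levels(self, name: str) -> list:
        """Sorted distinct levels of a factor column."""
        return sorted(self.predictors[name].unique().tolist())

    def to_csv(self, path, response_name: str = "response") -> None:
        out = self.predictors.copy()
        out.insert(0, response_name, self.y)
        out.to_csv(path, index=False)


def read_csv(path, response: str, factors: Sequence[str] = ()) -> ModelData:
    """Load a ModelData from a headed CSV file.

    ``response`` names the response column; ``factors`` forces numeric
    columns to be treated as categorical.
    """
    df = pd.read_csv(path)
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not in file")
    y = df[response].to_numpy(dtype=float)
    preds = df.drop(columns=[response])
    for f in factors:
        if f not in preds.columns:
            raise ValueError(f"factor column {f!r} not in file")
        preds[f] = preds[f].astype(str)
    return ModelData(y=y, predictors=preds, factors=frozenset(factors))


@dataclass(frozen=True)
class DesignMatrix:
    matrix: np.ndarray
    column_names: tuple[str, ...]
    coding: str = "treatment"

    def __post_init__(self):
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "column_names", tuple(self.column_names))
        if m.shape[1] != len(self.column_names):
            raise ValueError("column_names length mismatch")
        _check_full_rank(m, self.column_names)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def r(self) -> int:
        return self.matrix.shape[1]

    def drop(self, columns: Sequence) -> "DesignMatrix":
        """Return the sub-design with the named (or indexed) columns removed."""
        idx = self.column_indices(columns)
        keep = [j for j in range(self.r) if j not in idx]
        if not keep:
            raise ValueError("cannot drop every column of the design")
        return DesignMatrix(
            self.matrix[:, keep],
            tuple(self.column_names[j] for j in keep),
            self.coding,
        )

    def column_indices(self, columns: Sequence) -> list[int]:
        idx = []
        for c in columns:
            if isinstance(c, (int, np.integer)):
                j = int(c)
                if not 0 <= j < self.r:
                    raise ValueError(f"column index {j} out of range")
            else:
                try:
                    j = self.column_names.index(c)
                except ValueError:
                    raise ValueError(f"unknown design column {c!r}") from None
            idx.append(j)
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate columns in selection")
        return idx


def _check_full_rank(m: np.ndarray, names: Sequence[str]) -> None:
    if m.shape[1] > m.shape[0]:
        raise RankDeficientError(
            f"more columns ({m.shape[1]}) than observations ({m.shape[0]})"
        )
    sv = np.linalg.svd(m, compute_uv=False)
    if sv.size and sv[-1] <= RANK_RTOL * sv[0]:
        raise RankDeficientError(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(_aliased_columns(m, names))
        )


def _aliased_columns(m: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that are linear combinations of the columns before them."""
    aliased = []
    rank = 0
    for j in range(m.shape[1]):
        sub = m[:, : j + 1]
        sv = np.linalg.svd(sub, compute_uv=False)
        r = int(np.sum(sv > RANK_RTOL * sv[0]))
        if r == rank:
            aliased.append(str(names[j]))
        rank = r
    return aliased


# ---------------------------------------------------------------------------
# design construction


def _coded_columns(data: ModelData, name: str, coding: str):
    """Coded columns (list of 1-D arrays) and labels for one main effect."""
    col = data.predictors[name]
    if not data.is_factor(name):
        return [col.to_numpy(dtype=float)], [name]
    levels = data.levels(name)
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} needs at least 2 levels")
    counts = col.value_counts()
    if (counts < 1).any():  # pragma: no cover - unreachable with unique()
        raise ValueError(f"factor {name!r} has empty levels")
    cols, labels = [], []
    if coding == "treatment":
        # leave-one-column-out: indicators for every level but the first
        for lev in levels[1:]:
            cols.append((col == lev).to_numpy(dtype=float))
            labels.append(f"{name}[{lev}]")
    elif coding == "sum":
        last = levels[-1]
        for lev in levels[:-1]:
            v = (col == lev).to_numpy(dtype=float)
            v = v - (col == last).to_numpy(dtype=float)
            cols.append(v)
            labels.append(f"{name}[S.{lev}]")
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return cols, labels


def build_design(
    data: ModelData, terms: Sequence[str], coding: str = "treatment"
) -> DesignMatrix:
    """Build a full-rank design matrix from a list of model terms.

    Terms are ``"1"`` (intercept), a predictor name, or ``"a:b"`` for the
    interaction of two previously declared main effects (elementwise
    products of their coded columns).  With two factors of l1 and l2
    levels and the full term list, the column count is l1*l2.
    """
    n = data.n
    cols: list[np.ndarray] = []
    names: list[str] = []
    main_cols: dict[str, tuple[list[np.ndarray], list[str]]] = {}
    for term in terms:
        term = term.strip()
        if term == "1":
            cols.append(np.ones(n))
            names.append("Intercept")
        elif ":" in term:
            a, b = (t.strip() for t in term.split(":", 1))
            for t in (a, b):
                if t not in main_cols:
                    raise ValueError(
                        f"interaction {term!r} references {t!r} before its "
                        "main effect is declared"
                    )
            ca, la = main_cols[a]
            cb, lb = main_cols[b]
            for va, na in zip(ca, la):
                for vb, nb in zip(cb, lb):
                    cols.append(va * vb)
                    names.append(f"{na}:{nb}")
        else:
            if term not in data.predictors.columns:
                raise ValueError(f"unknown term {term!r}")
            c, l = _coded_columns(data, term, coding)
            main_cols[term] = (c, l)
            cols.extend(c)
            names.extend(l)
    if not cols:
        raise ValueError("empty term list")
    return DesignMatrix(np.column_stack(cols), tuple(names), coding)


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class LinearModelFit:
    """Maximum-likelihood (= least-squares) fit of one linear model.

    ``sigma2_ml`` is RSS/n; the unbiased variance estimate RSS/(n-r) is
    exposed as a property and raises on a saturated fit.  The maximized
    log-likelihood is -(n/2)(log(2 pi sigma2_ml) + 1).
    """

    beta_hat: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    sigma2_ml: float
    n: int
    r: int
    design: DesignMatrix

    @property
    def sigma2_unbiased(self) -> float:
        if self.n == self.r:
            raise DegenerateFitError(
                "sigma2_unbiased undefined for a saturated fit (n == r)"
            )
        return self.n * self.sigma2_ml / (self.n - self.r)

    @property
    def loglik_max(self) -> float:
        if self.sigma2_ml == 0.0:
            return math.inf
        return -0.5 * self.n * (math.log(2.0 * math.pi * self.sigma2_ml) + 1.0)

    @property
    def rss(self) -> float:
        return self.n * self.sigma2_ml

    def to_dict(self) -> dict:
        return {
            "beta_hat": self.beta_hat.tolist(),
            "column_names": list(self.design.column_names),
            "sigma2_ml": self.sigma2_ml,
            "sigma2_unbiased": None if self.n == self.r else self.sigma2_unbiased,
            "loglik_max": self.loglik_max,
            "n": self.n,
            "r": self.r,
        }


def fit(data: ModelData, design: DesignMatrix) -> LinearModelFit:
    """ML / least-squares fit of ``y ~ N(X beta, sigma^2 I)``."""
    X = design.matrix
    if X.shape[0] != data.n:
        raise ValueError("design and data disagree on n")
    beta, _, _, _ = np.linalg.lstsq(X, data.y, rcond=None)
    fitted = X @ beta
    resid = data.y - fitted
    rss = float(resid @ resid)
    # snap numerically-perfect fits to exactly zero so degenerate-variance
    # behaviour is deterministic rather than round-off-dependent
    scale = float(data.y @ data.y)
    if rss <= 1e-24 * scale:
        rss = 0.0
        resid = np.zeros_like(resid)
    sigma2_ml = max(rss, 0.0) / data.n
    return LinearModelFit(
        beta_hat=beta,
        fitted=fitted,
        residuals=resid,
        sigma2_ml=sigma2_ml,
        n=data.n,
        r=design.r,
        design=design,
    )


# ---------------------------------------------------------------------------
# nested comparisons


@dataclass(frozen=True)
class ContrastSpec:
    """q linear constraints L beta = h on the full-model coefficients."""

    L: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        L = np.atleast_2d(np.asarray(self.L, dtype=float))
        h = np.atleast_1d(np.asarray(self.h, dtype=float))
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "h", h)
        if L.shape[0] != h.shape[0]:
            raise ValueError("L and h disagree on the number of constraints")
        if np.linalg.matrix_rank(L) < L.shape[0]:
            raise RankDeficientError("constraint matrix L is not full row rank")

    @property
    def q(self) -> int:
        return self.L.shape[0]


@dataclass(frozen=True)
class NestedComparison:
    """F statistic and likelihood-ratio summary for model 1 within model 2."""

    n: int
    r: int
    q: int
    F: float
    p_central: float
    ss_table: pd.DataFrame | None = None

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.n - self.r < 1:
            raise ValueError("need n - r >= 1 residual degrees of freedom")

    @property
    def G2(self) -> float:
        return self.n * math.log1p(self.q * self.F / (self.n - self.r))

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "r": self.r,
            "q": self.q,
            "F": self.F,
            "G2": self.G2,
            "p_central": self.p_central,
        }
        if self.ss_table is not None:
            d["ss_table"] = json.loads(self.ss_table.to_json(orient="index"))
        return d


def _comparison_from_rss(
    rss1: float, rss2: float, n: int, r: int, q: int
) -> NestedComparison:
    if n <= r:
        raise DegenerateFitError("full model is saturated; F undefined")
    if rss2 <= 0.0:
        if rss1 <= 0.0:
            # both models fit perfectly: likelihood ratio 1, F = 0
            return NestedComparison(n=n, r=r, q=q, F=0.0, p_central=1.0)
        raise DegenerateFitError("full-model residual sum of squares is zero")
    F = max(rss1 - rss2, 0.0) / q / (rss2 / (n - r))
    p = float(stats.f.sf(F, q, n - r))
    return NestedComparison(n=n, r=r, q=q, F=F, p_central=p)


def compare_nested_A(
    data: ModelData, design_full: DesignMatrix, dropped_columns: Sequence
) -> NestedComparison:
    """Formulation A: test beta_2 = 0 by dropping design columns.

    ``dropped_columns`` (names or indices) form X2; the remaining
    columns X1 must still be full rank.
    """
    idx = design_full.column_indices(dropped_columns)
    q = len(idx)
    if q == design_full.r:
        raise ValueError("cannot drop all columns: no null model remains")
    reduced = design_full.drop(idx)
    f2 = fit(data, design_full)
    f1 = fit(data, reduced)
    return _comparison_from_rss(f1.rss, f2.rss, data.n, design_full.r, q)


def compare_nested_B(
    data: ModelData, design: DesignMatrix, contrast: ContrastSpec
) -> NestedComparison:
    """Formulation B: test the linear constraints L beta = h directly."""
    X = design.matrix
    if contrast.L.shape[1] != design.r:
        raise ValueError("L has wrong number of columns for this design")
    f2 = fit(data, design)
    XtX = X.T @ X
    diff = contrast.L @ f2.beta_hat - contrast.h
    M = contrast.L @ np.linalg.solve(XtX, contrast.L.T)
    quad = float(diff @ np.linalg.solve(M, diff))
    n, r, q = data.n, design.r, contrast.q
    if n <= r:
        raise DegenerateFitError("full model is saturated; F undefined")
    if f2.rss <= 0.0:
        raise DegenerateFitError("full-model residual sum of squares is zero")
    F = max(quad, 0.0) / q / (f2.rss / (n - r))
    return NestedComparison(
        n=n, r=r, q=q, F=F, p_central=float(stats.f.sf(F, q, n - r))
    )


def anova_table(data: ModelData, factor_terms: Sequence[str]) -> pd.DataFrame:
    """Sequential (type-I) ANOVA decomposition over ordered factor terms.

    Columns: df, SS, MS, F, p, with an ``Error`` row from the full model.
    Main-effect entries must be factors; interaction terms ``a:b`` are
    allowed once their main effects appear earlier in the list.
    """
    for term in factor_terms:
        parts = term.split(":")
        for p in parts:
            p = p.strip()
            if p not in data.predictors.columns:
                raise ValueError(f"unknown term {p!r}")
            if not data.is_factor(p):
                raise ValueError(f"{p!r} is not a factor")
    terms_so_far = ["1"]
    rss_prev = fit(data, build_design(data, terms_so_far)).rss
    r_prev = 1
    rows = []
    for term in factor_terms:
        terms_so_far = terms_so_far + [term]
        d = build_design(data, terms_so_far)
        rss = fit(data, d).rss
        rows.append((term, d.r - r_prev, rss_prev - rss))
        rss_prev, r_prev = rss, d.r
    n, r_full = data.n, r_prev
    if n <= r_full:
        raise DegenerateFitError("saturated model: no error degrees of freedom")
    mse = rss_prev / (n - r_full)
    out = []
    for term, df, ss in rows:
        ms = ss / df
        F = ms / mse if mse > 0 else np.nan
        p = float(stats.f.sf(F, df, n - r_full)) if mse > 0 else np.nan
        out.append({"df": df, "SS": ss, "MS": ms, "F": F, "p": p})
    idx = list(factor_terms) + ["Error"]
    out.append(
        {"df": n - r_full, "SS": rss_prev, "MS": mse, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(out, index=idx)
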