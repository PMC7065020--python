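"""Lande-Arnold phenotypic selection analysis.

Total selection on a trait is the *selection differential* S, the OLS slope
of relative fitness w on the single standardized trait z.  Direct selection
is measured by *selection gradients*: the linear (directional) gradients
beta are the partial regression coefficients of w on all traits jointly in a
first-order model, while nonlinear gradients come from the full second-order
model

    w ~ 1 + sum_j b_j z_j + sum_j q_j z_j^2 + sum_{i<j} c_ij z_i z_j .

The quadratic gradient matrix gamma has diagonal gamma_jj = 2 q_j (the
fitted quadratic coefficient is half the surface curvature, so it is
doubled, and so is its standard error) and off-diagonal gamma_ij = c_ij
(cross-product coefficients already estimate the correlational gradient and
are *not* doubled).  Because S folds in indirect selection through trait
correlations, S = P beta where P is the phenotypic correlation matrix of the
standardized traits — an identity this module exposes directly.

A significant negative quadratic gradient only demonstrates stabilizing
selection if the fitted fitness maximum lies inside the observed trait
range (Mitchell-Olds & Shaw criterion); :func:`stabilizing_check` reports
that vertex diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .data import TRAITS, AnalysisTable, DegenerateTraitError

POOLED = "pooled"


class CollinearityError(ValueError):
    """Design matrix is rank-deficient on the complete-case set."""


class UnderdeterminedModelError(ValueError):
    """Fewer complete cases than model terms."""


def significance_stars(p: float) -> str:
    """Display stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def group_frame(table: AnalysisTable, group: str) -> pd.DataFrame:
    """Rows belonging to one treatment group, or all rows for ``pooled``."""
    if group == POOLED:
        return table.df
    if group not in table.treatment_levels:
        raise KeyError(f"unknown group {group!r}; expected one of "
                       f"{table.treatment_levels + (POOLED,)}")
    return table.df[table.df["treatment"] == group]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name near-dependent columns via pairwise correlation of non-constant cols
        sub = X[:, 1:]
        dependent = []
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(sub, rowvar=False)
        for i, j in combinations(range(sub.shape[1]), 2):
            if np.isfinite(C[i, j]) and abs(C[i, j]) > 1 - 1e-8:
                dependent.append((names[i + 1], names[j + 1]))
        raise CollinearityError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"dependent column pairs: {dependent or 'unidentified'}"
        )


def quadratic_design(Z: pd.DataFrame, traits: Sequence[str]) -> pd.DataFrame:
    """Second-order design columns in fixed order: linear, squared, cross."""
    cols = {}
    for t in traits:
        cols[f"z_{t}"] = Z[f"z_{t}"]
    for t in traits:
        cols[f"z_{t}^2"] = Z[f"z_{t}"] ** 2
    for a, b in combinations(traits, 2):
        cols[f"z_{a}:z_{b}"] = Z[f"z_{a}"] * Z[f"z_{b}"]
    return pd.DataFrame(cols, index=Z.index)


class LandeArnoldRegression(BaseEstimator, RegressorMixin):
    """OLS fitness regression on standardized traits.

    Parameters
    ----------
    traits
        Trait names, defining the column order of ``Z`` and of the fitted
        coefficient vectors/matrix.
    order
        ``"linear"`` fits the first-order model and exposes ``beta_``;
        ``"quadratic"`` fits the full second-order model and exposes
        ``gamma_`` (diagonal doubled) alongside the linear terms of that
        model.  Gradient reporting convention: take beta from the linear
        fit and gamma from the quadratic fit.

    Attributes
    ----------
    beta_ : ndarray of shape (k,)
        Linear coefficients of the fitted model.
    gamma_ : ndarray of shape (k, k)
        Symmetric quadratic/correlational gradient matrix (quadratic fit
        only).
    n_used_ : int
        Complete cases used.
    """

    def __init__(self, traits: Sequence[str] = TRAITS, order: str = "linear"):
        self.traits = traits
        self.order = order

    def fit(self, Z, w) -> "LandeArnoldRegression":
        if self.order not in ("linear", "quadratic"):
            raise ValueError("order must be 'linear' or 'quadratic'")
        k = len(self.traits)
        Z = pd.DataFrame(np.asarray(Z, float),
                         columns=[f"z_{t}" for t in self.traits]) \
            if not isinstance(Z, pd.DataFrame) else Z
        w = np.asarray(w, float)
        X = Z if self.order == "linear" else quadratic_design(Z, self.traits)
        n_terms = 1 + X.shape[1]
        if len(w) <= n_terms - 1 or (self.order == "quadratic" and len(w) <= n_terms):
            raise UnderdeterminedModelError(
                f"{len(w)} cases for {n_terms} model terms")
        Xd = sm.add_constant(X, has_constant="add")
        _check_rank(np.asarray(Xd, float), list(Xd.columns))
        res = sm.OLS(w, Xd).fit()
        self.result_ = res
        self.n_used_ = int(res.nobs)
        lin_names = [f"z_{t}" for t in self.traits]
        self.intercept_ = float(res.params["const"])
        self.beta_ = res.params[lin_names].to_numpy()
        self.beta_se_ = res.bse[lin_names].to_numpy()
        self.beta_pvalues_ = res.pvalues[lin_names].to_numpy()
        if self.order == "quadratic":
            gamma = np.zeros((k, k))
            gse = np.zeros((k, k))
            gp = np.zeros((k, k))
            quad_raw = np.zeros(k)
            for j, t in enumerate(self.traits):
                name = f"z_{t}^2"
                quad_raw[j] = res.params[name]
                gamma[j, j] = 2.0 * res.params[name]   # doubled quadratic coef
                gse[j, j] = 2.0 * res.bse[name]        # SE doubled alongside
                gp[j, j] = res.pvalues[name]           # test of the raw coef
            for (i, a), (j, b) in combinations(enumerate(self.traits), 2):
                name = f"z_{a}:z_{b}"
                gamma[i, j] = gamma[j, i] = res.params[name]
                gse[i, j] = gse[j, i] = res.bse[name]
                gp[i, j] = gp[j, i] = res.pvalues[name]
            self.quadratic_raw_ = quad_raw
            self.gamma_ = gamma
            self.gamma_se_ = gse
            self.gamma_pvalues_ = gp
        return self

    def predict(self, Z) -> np.ndarray:
        Z = pd.DataFrame(np.asarray(Z, float),
                         columns=[f"z_{t}" for t in self.traits]) \
            if not isinstance(Z, pd.DataFrame) else Z
        X = Z if self.order == "linear" else quadratic_design(Z, self.traits)
        Xd = sm.add_constant(X, has_constant="add")
        return np.asarray(self.result_.predict(Xd))


@dataclass
class DifferentialResult:
    trait: str
    group: str
    S: float
    se: float
    t: float
    p: float
    n_used: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass
class GradientsResult:
    traits: tuple[str, ...]
    group: str
    beta: np.ndarray
    beta_se: np.ndarray
    beta_p: np.ndarray
    n_used: int
    gamma: np.ndarray | None = None
    gamma_se: np.ndarray | None = None
    gamma_p: np.ndarray | None = None
    quadratic_raw: np.ndarray | None = None
    n_used_quadratic: int | None = None
    P: np.ndarray | None = None

    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trait": self.traits, "group": self.group, "beta": self.beta,
            "se": self.beta_se, "p": self.beta_p,
            "stars": [significance_stars(p) for p in self.beta_p],
            "n_used": self.n_used,
        })

    def gamma_frame(self) -> pd.DataFrame:
        if self.gamma is None:
            raise ValueError("no quadratic fit present")
        rows = []
        k = len(self.traits)
        for i in range(k):
            for j in range(i, k):
                rows.append({
                    "term": (f"{self.traits[i]}^2" if i == j
                             else f"{self.traits[i]}:{self.traits[j]}"),
                    "group": self.group,
                    "gamma": self.gamma[i, j],
                    "se": self.gamma_se[i, j],
                    "p": self.gamma_p[i, j],
                    "stars": significance_stars(self.gamma_p[i, j]),
                    "n_used": self.n_used_quadratic,
                })
        return pd.DataFrame(rows)


def selection_differential(
    table: AnalysisTable, trait: str, group: str = POOLED
) -> DifferentialResult:
    """Total selection S on one trait: slope of w on z within ``group``."""
    df = group_frame(table, group).dropna(subset=[f"z_{trait}", "w"])
    if len(df) < 3:
        raise UnderdeterminedModelError(
            f"{len(df)} complete cases for trait {trait!r} in group {group!r}")
    z = df[f"z_{trait}"].to_numpy()
    if np.ptp(z) == 0:
        raise DegenerateTraitError(f"trait {trait!r} constant in group {group!r}")
    res = sm.OLS(df["w"].to_numpy(), sm.add_constant(z)).fit()
    return DifferentialResult(
        trait=trait, group=group, S=float(res.params[1]), se=float(res.bse[1]),
        t=float(res.tvalues[1]), p=float(res.pvalues[1]), n_used=int(res.nobs))


def differentials_table(
    table: AnalysisTable, traits: Sequence[str] = TRAITS,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All differentials, one row per trait x group."""
    if groups is None:
        groups = list(table.treatment_levels) + [POOLED]
    rows = []
    for trait in traits:
        for group in groups:
            r = selection_differential(table, trait, group)
            rows.append({"trait": trait, "group": group, "S": r.S, "se": r.se,
                         "t": r.t, "p": r.p, "stars": r.stars, "n_used": r.n_used})
    return pd.DataFrame(rows)


def linear_gradients(
    table: AnalysisTable, traits: Sequence[str] = TRAITS, group: str = POOLED
) -> GradientsResult:
    """Directional gradients beta from the linear-terms-only model."""
    cols = [f"z_{t}" for t in traits]
    df = group_frame(table, group).dropna(subset=cols + ["w"])
    est = LandeArnoldRegression(traits=traits, order="linear").fit(df[cols], df["w"])
    return GradientsResult(
        traits=tuple(traits), group=group, beta=est.beta_, beta_se=est.beta_se_,
        beta_p=est.beta_pvalues_, n_used=est.n_used_)


def quadratic_gradients(
    table: AnalysisTable, traits: Sequence[str] = TRAITS, group: str = POOLED
) -> GradientsResult:
    """Full second-order fit; gamma with doubled diagonal, beta from the
    separate linear fit (two-model reporting convention)."""
    lin = linear_gradients(table, traits, group)
    cols = [f"z_{t}" for t in traits]
    df = group_frame(table, group).dropna(subset=cols + ["w"])
    est = LandeArnoldRegression(traits=traits, order="quadratic").fit(df[cols], df["w"])
    lin.gamma = est.gamma_
    lin.gamma_se = est.gamma_se_
    lin.gamma_p = est.gamma_pvalues_
    lin.quadratic_raw = est.quadratic_raw_
    lin.n_used_quadratic = est.n_used_
    return lin


def selection_decomposition(
    table: AnalysisTable, traits: Sequence[str] = TRAITS, group: str = POOLED
) -> dict:
    """S, beta and the phenotypic correlation matrix P on one shared
    complete-case set, restandardized within that set so the decomposition
    S = P beta holds as an exact identity.

    This is the algebra behind "direct vs indirect selection": when S_j is
    close to beta_j, most selection on trait j is direct rather than
    channelled through correlated traits.
    """
    cols = [f"z_{t}" for t in traits]
    df = group_frame(table, group).dropna(subset=cols + ["w"]).copy()
    for c in cols:
        v = df[c]
        df[c] = (v - v.mean()) / v.std(ddof=1)
    Z = df[cols].to_numpy()
    w = df["w"].to_numpy()
    P = np.cov(Z, rowvar=False, ddof=1)
    S = np.array([sm.OLS(w, sm.add_constant(Z[:, [j]])).fit().params[1]
                  for j in range(len(traits))])
    beta = sm.OLS(w, sm.add_constant(Z)).fit().params[1:]
    return {"traits": tuple(traits), "group": group, "S": S,
            "beta": np.asarray(beta), "P": P, "n_used": len(df)}


@dataclass
class StabilizingDiagnosis:
    """Vertex diagnosis of the 1-D quadratic fitness fit w = a + b z + c z^2."""

    trait: str
    group: str
    a: float
    b: float
    c: float
    c_se: float
    c_p: float
    z_range: tuple[float, float]
    vertex: float | None
    interior: bool
    curvature: str  # "concave" (c < 0), "convex" or "flat"
    grid: pd.DataFrame = field(repr=False, default=None)


def stabilizing_check(
    table: AnalysisTable, trait: str, group: str = POOLED, n_grid: int = 101
) -> StabilizingDiagnosis:
    """Does negative curvature reflect a true intermediate optimum?

    Fits w on (z, z^2) within the group, locates the parabola vertex
    z* = -b/(2c), and flags whether z* lies strictly inside the observed z
    range when the fit is concave.  Also returns the fitted curve with a
    pointwise 95% confidence band for plotting.
    """
    df = group_frame(table, group).dropna(subset=[f"z_{trait}", "w"])
    z = df[f"z_{trait}"].to_numpy()
    w = df["w"].to_numpy()
    X = sm.add_constant(np.column_stack([z, z ** 2]))
    res = sm.OLS(w, X).fit()
    a, b, c = map(float, res.params)
    lo, hi = float(z.min()), float(z.max())
    zg = np.linspace(lo, hi, n_grid)
    pred = res.get_prediction(sm.add_constant(np.column_stack([zg, zg ** 2])))
    band = pred.conf_int(alpha=0.05)
    grid = pd.DataFrame({"z": zg, "w_fit": pred.predicted_mean,
                         "ci_low": band[:, 0], "ci_high": band[:, 1]})
    if c < 0:
        vertex = -b / (2.0 * c)
        interior = bool(lo < vertex < hi)
        curvature = "concave"
    else:
        vertex = (-b / (2.0 * c)) if c > 0 else None
        interior = False
        curvature = "convex" if c > 0 else "flat"
    return StabilizingDiagnosis(
        trait=trait, group=group, a=a, b=b, c=c,
        c_se=float(res.bse[2]), c_p=float(res.pvalues[2]),
        z_range=(lo, hi), vertex=vertex, interior=interior,
        curvature=curvature, grid=grid)
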