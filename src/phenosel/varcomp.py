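"""REML variance partitioning for genotype x environment designs.

For each trait y the model is

    y = X b + Z_g u_g + Z_gt u_gt + e,
    u_g ~ N(0, sigma2_g I),  u_gt ~ N(0, sigma2_gxe I),  e ~ N(0, sigma2_e I),

with treatment as the fixed effect and genotype (maternal line) and
genotype-by-treatment as crossed random effects.  Estimation maximizes the
restricted (REML) likelihood, profiled so the search runs over the two
variance *ratios* phi = sigma2/sigma2_e on the non-negative orthant while
sigma2_e is solved in closed form.  The marginal covariance is handled via
the Woodbury identity on the q-dimensional random-effect space (q <= 3 x
n_genotypes), so each likelihood evaluation costs O(n q^2).

Inference mirrors standard mixed-model practice: random terms are tested by
the REML likelihood-ratio chi-square against a chi^2(1) reference (the
conservative convention; a 50:50 boundary-mixture reference is available),
and the fixed treatment contrast by an F statistic with
Satterthwaite-approximated denominator degrees of freedom,

    df2 = 2 Var(c'b)^2 / Var[Var-hat(c'b)],

where the variance of the estimated contrast variance is obtained by the
delta method over the variance components, using numerical derivatives and
the inverse of the observed REML information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from .data import AnalysisTable, PhenotypeTable

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class EstimationError(RuntimeError):
    """REML optimization failed to converge; carries best-so-far state."""

    def __init__(self, message: str, best: dict | None = None):
        super().__init__(message)
        self.best = best


class DesignError(ValueError):
    """The fixed/random design is singular or too small to fit."""


@dataclass
class VarianceComponents:
    """Fitted variance partition for one trait (a Table-1-style row)."""

    trait: str
    transform: str
    sigma2_g: float
    sigma2_gxe: float
    sigma2_e: float
    fixed_effects: dict[str, float]
    fixed_se: dict[str, float]
    loglik: float
    converged: bool
    grad_norm: float
    n_used: int
    chi2_g: float | None = None
    p_g: float | None = None
    chi2_gxe: float | None = None
    p_gxe: float | None = None
    f_treatment: float | None = None
    df1: int | None = None
    df2: float | None = None
    p_treatment: float | None = None


def _dummies(labels: np.ndarray) -> np.ndarray:
    cats = pd.unique(labels)
    return (labels[:, None] == cats[None, :]).astype(float)


class VarianceComponentsREML(BaseEstimator):
    """Profiled-REML estimator for the crossed genotype/treatment design.

    Parameters
    ----------
    genotype_col, treatment_col
        Grouping columns.  ``treatment_col=None`` drops the fixed treatment
        effect (intercept-only fixed part) and the G x E term.
    include_genotype, include_gxe
        Which random terms to fit; disabling one gives the nested reduction
        used by the likelihood-ratio test.
    n_restarts
        Extra optimizer starts beyond the moment-based one.

    Attributes
    ----------
    sigma2_g_, sigma2_gxe_, sigma2_e_ : float
        REML variance-component estimates (0 when the term is excluded).
    loglik_ : float
        Maximized restricted log-likelihood (full constant included, so
        differences between nested fits are the LRT statistic).
    fixed_effects_, fixed_se_ : dict
    converged_ : bool
    """

    def __init__(self, genotype_col: str = "genotype",
                 treatment_col: str | None = "treatment",
                 include_genotype: bool = True, include_gxe: bool = True,
                 n_restarts: int = 3, tol: float = 1e-12):
        self.genotype_col = genotype_col
        self.treatment_col = treatment_col
        self.include_genotype = include_genotype
        self.include_gxe = include_gxe
        self.n_restarts = n_restarts
        self.tol = tol

    # -- internal linear algebra -------------------------------------------

    def _prepare(self, df: pd.DataFrame, response: str) -> None:
        df = df.dropna(subset=[response, self.genotype_col] +
                       ([self.treatment_col] if self.treatment_col else []))
        self._geno_labels = df[self.genotype_col].to_numpy()
        self._treat_labels = (df[self.treatment_col].to_numpy()
                              if self.treatment_col else None)
        y = df[response].to_numpy(float)
        n = len(y)
        if n < 4:
            raise DesignError(f"only {n} complete cases for {response!r}")
        geno = df[self.genotype_col].to_numpy()
        if pd.unique(geno).size < 2:
            raise DesignError("need >= 2 genotypes")
        X = [np.ones(n)]
        self._fixed_names = ["intercept"]
        if self.treatment_col:
            tr = df[self.treatment_col].to_numpy()
            levels = pd.unique(tr)
            if levels.size != 2:
                raise DesignError(f"expected 2 treatment levels, got {levels.size}")
            # indicator of the lexicographically smaller-index level seen first;
            # reference is the second level encountered
            X.append((tr == levels[0]).astype(float))
            self._fixed_names.append(f"treatment[{levels[0]}]")
        self._X = np.column_stack(X)
        if np.linalg.matrix_rank(self._X) < self._X.shape[1]:
            raise DesignError("singular fixed-effect design")
        self._y = y
        self._n = n
        self._p = self._X.shape[1]
        blocks = []
        self._terms = []
        if self.include_genotype:
            blocks.append(_dummies(geno))
            self._terms.append("genotype")
        if self.include_gxe:
            if not self.treatment_col:
                raise DesignError("gxe term requires a treatment column")
            inter = np.char.add(np.char.add(geno.astype(str), "||"),
                                df[self.treatment_col].to_numpy().astype(str))
            blocks.append(_dummies(inter))
            self._terms.append("gxe")
        self._Zs = blocks

    def _profiled(self, phi: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
        """Profiled REML criterion at variance ratios ``phi``.

        Returns (restricted loglik, sigma2_e-hat, beta-hat, cov_beta/sigma2_e).
        """
        X, y, n, p = self._X, self._y, self._n, self._p
        cols = [np.sqrt(max(f, 0.0)) * Z for f, Z in zip(phi, self._Zs) if f > 0]
        if cols:
            Z = np.hstack(cols)
            S = Z.T @ Z + np.eye(Z.shape[1])
            cf = linalg.cho_factor(S, lower=True)
            logdetH = 2.0 * np.log(np.diag(cf[0])).sum()
            ZtX, Zty = Z.T @ X, Z.T @ y
            XtHX = X.T @ X - ZtX.T @ linalg.cho_solve(cf, ZtX)
            XtHy = X.T @ y - ZtX.T @ linalg.cho_solve(cf, Zty)
            ytHy = y @ y - Zty @ linalg.cho_solve(cf, Zty)
        else:
            logdetH = 0.0
            XtHX, XtHy, ytHy = X.T @ X, X.T @ y, y @ y
        cfx = linalg.cho_factor(XtHX)
        beta = linalg.cho_solve(cfx, XtHy)
        qform = float(ytHy - XtHy @ beta)
        qform = max(qform, 1e-300)
        sigma2_e = qform / (n - p)
        _, logdetXtHX = np.linalg.slogdet(XtHX)
        ll = -0.5 * ((n - p) * (_LOG2PI + np.log(sigma2_e) + 1.0)
                     + logdetH + logdetXtHX)
        cov_beta = linalg.cho_solve(cfx, np.eye(p))
        return ll, sigma2_e, beta, cov_beta

    def reml_loglik(self, theta: np.ndarray) -> float:
        """Restricted log-likelihood at absolute variance components
        ``theta = (sigma2 per included random term ..., sigma2_e)``."""
        sigma2_e = float(theta[-1])
        phi = np.asarray(theta[:-1], float) / sigma2_e
        X, n, p = self._X, self._n, self._p
        cols = [np.sqrt(max(f, 0.0)) * Z for f, Z in zip(phi, self._Zs) if f > 0]
        if cols:
            Z = np.hstack(cols)
            S = Z.T @ Z + np.eye(Z.shape[1])
            cf = linalg.cho_factor(S, lower=True)
            logdetH = 2.0 * np.log(np.diag(cf[0])).sum()
            ZtX, Zty = Z.T @ X, Z.T @ self._y
            XtHX = X.T @ X - ZtX.T @ linalg.cho_solve(cf, ZtX)
            XtHy = X.T @ self._y - ZtX.T @ linalg.cho_solve(cf, Zty)
            ytHy = self._y @ self._y - Zty @ linalg.cho_solve(cf, Zty)
        else:
            logdetH = 0.0
            XtHX, XtHy = X.T @ X, X.T @ self._y
            ytHy = self._y @ self._y
        cfx = linalg.cho_factor(XtHX)
        beta = linalg.cho_solve(cfx, XtHy)
        qform = float(ytHy - XtHy @ beta)
        _, logdetXtHX = np.linalg.slogdet(XtHX)
        return -0.5 * ((n - p) * _LOG2PI + (n - self._p) * np.log(sigma2_e)
                       + logdetH + logdetXtHX + qform / sigma2_e)

    def contrast_variance(self, theta: np.ndarray, c: np.ndarray) -> float:
        """Var(c' beta-hat) = c' (X' V^-1 X)^-1 c at variance components theta."""
        sigma2_e = float(theta[-1])
        phi = np.asarray(theta[:-1], float) / sigma2_e
        _, _, _, cov_unit = self._profiled(phi)
        return float(c @ (sigma2_e * cov_unit) @ c)

    # -- fitting -----------------------------------------------------------

    def fit(self, data: AnalysisTable | PhenotypeTable | pd.DataFrame,
            response: str = "flowering_day") -> "VarianceComponentsREML":
        df = data.df if hasattr(data, "df") else data
        self._prepare(df, response)
        self.response_ = response
        k = len(self._Zs)
        if k == 0:
            ll, s2e, beta, cov = self._profiled(np.zeros(0))
            self._finalize(np.zeros(0), ll, s2e, beta, cov, True, 0.0)
            return self

        var_y = float(np.var(self._y, ddof=1))
        s2e0 = max(var_y, 1e-12)
        mom = np.full(k, 0.5)
        starts = [mom, np.full(k, 1e-4), np.full(k, 2.0)]
        rng = np.random.default_rng(0)
        for _ in range(max(0, self.n_restarts - len(starts) + 1)):
            starts.append(np.exp(rng.normal(0, 1, k)))

        def negll(phi):
            return -self._profiled(phi)[0]

        best = None
        for x0 in starts[: self.n_restarts + 1]:
            res = optimize.minimize(
                negll, x0, method="L-BFGS-B",
                bounds=[(0.0, 1e6)] * k,
                options={"ftol": self.tol, "gtol": 1e-10, "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise EstimationError("REML optimization failed",
                                  best=None if best is None else dict(best))
        phi = np.clip(best.x, 0.0, None)
        phi[phi < 1e-10] = 0.0
        ll, s2e, beta, cov_unit = self._profiled(phi)
        # projected-gradient check: boundary components only count when the
        # criterion wants to decrease them further
        h = 1e-6
        pg = np.zeros(k)
        for i in range(k):
            xp, xm = phi.copy(), phi.copy()
            xp[i] += h
            xm[i] = max(xm[i] - h, 0.0)
            g = (negll(xp) - negll(xm)) / (xp[i] - xm[i])
            pg[i] = min(g, 0.0) if phi[i] == 0.0 else g
        grad_norm = float(np.linalg.norm(pg))
        converged = bool(best.success) or grad_norm < 1e-4
        if not converged:
            logger.warning("REML optimizer flagged non-convergence for %r "
                           "(projected grad norm %.3g); keeping best state",
                           response, grad_norm)
        self._finalize(phi, ll, s2e, beta, s2e * cov_unit, converged, grad_norm)
        return self

    def _finalize(self, phi, ll, s2e, beta, cov_beta, converged, grad_norm) -> None:
        comps = dict(zip(self._terms, phi * s2e))
        self.sigma2_g_ = float(comps.get("genotype", 0.0))
        self.sigma2_gxe_ = float(comps.get("gxe", 0.0))
        self.sigma2_e_ = float(s2e)
        self.phi_ = np.asarray(phi, float)
        self.loglik_ = float(ll)
        self.fixed_effects_ = dict(zip(self._fixed_names, map(float, beta)))
        self.fixed_se_ = dict(zip(self._fixed_names,
                                  map(float, np.sqrt(np.diag(cov_beta)))))
        self.converged_ = converged
        self.grad_norm_ = float(grad_norm)
        self.n_used_ = self._n

    @property
    def theta_(self) -> np.ndarray:
        """(included random-term variances ..., sigma2_e)."""
        vals = {"genotype": self.sigma2_g_, "gxe": self.sigma2_gxe_}
        return np.array([vals[t] for t in self._terms] + [self.sigma2_e_])

    # -- inference ---------------------------------------------------------

    def lrt(self, term: str, boundary_mixture: bool = False) -> tuple[float, float]:
        """REML likelihood-ratio test for dropping one random term.

        chi2 = 2 (ll_full - ll_reduced), clipped at zero; p from chi^2(1)
        (or the 50:50 chi^2(0):chi^2(1) mixture if requested).
        """
        if term not in self._terms:
            raise KeyError(f"term {term!r} not in fitted model {self._terms}")
        reduced = VarianceComponentsREML(
            genotype_col=self.genotype_col, treatment_col=self.treatment_col,
            include_genotype=self.include_genotype and term != "genotype",
            include_gxe=self.include_gxe and term != "gxe",
            n_restarts=self.n_restarts, tol=self.tol)
        reduced.fit(self._frame(), self.response_)
        chi2 = max(0.0, 2.0 * (self.loglik_ - reduced.loglik_))
        p = float(stats.chi2.sf(chi2, df=1))
        if boundary_mixture:
            p = 0.5 * p if chi2 > 0 else 1.0
        return chi2, p

    def _frame(self) -> pd.DataFrame:
        cols = {self.response_: self._y, self.genotype_col: self._geno_labels}
        if self.treatment_col:
            cols[self.treatment_col] = self._treat_labels
        return pd.DataFrame(cols)

    def satterthwaite_f(self, rel_step: float = 1e-5,
                        boundary_tol: float = 1e-8) -> dict:
        """F test of the treatment contrast with Satterthwaite df2.

        df2 = 2 Var(c)^2 / (g' I^-1 g), with g the numerical gradient of
        Var-hat(c' beta) over the variance components and I the observed REML
        information (negative Hessian), both by central differences.
        Components estimated at the zero boundary are held out of the delta
        method.  If the information matrix cannot be inverted, df2 falls back
        to the OLS residual df with a logged warning.
        """
        if self.treatment_col is None:
            raise DesignError("no treatment contrast in an intercept-only model")
        name = self._fixed_names[1]
        est, se = self.fixed_effects_[name], self.fixed_se_[name]
        F = (est / se) ** 2
        c = np.zeros(self._p)
        c[1] = 1.0
        theta = self.theta_
        scale = max(self.sigma2_e_, 1e-12)
        active = [i for i in range(len(theta))
                  if theta[i] > boundary_tol * scale or i == len(theta) - 1]
        var_c = self.contrast_variance(theta, c)

        def var_at(t_active):
            t = theta.copy()
            t[active] = np.clip(t_active, 1e-300, None)
            return self.contrast_variance(t, c)

        def ll_at(t_active):
            t = theta.copy()
            t[active] = np.clip(t_active, 1e-300, None)
            return self.reml_loglik(t)

        t0 = theta[active]
        h = rel_step * np.maximum(np.abs(t0), scale)
        m = len(active)
        grad = np.zeros(m)
        for i in range(m):
            tp, tm = t0.copy(), t0.copy()
            tp[i] += h[i]
            tm[i] = max(tm[i] - h[i], 0.0)
            grad[i] = (var_at(tp) - var_at(tm)) / (tp[i] - tm[i])
        hess = np.zeros((m, m))
        hstep = np.sqrt(np.maximum(h, 1e-12)) * np.sqrt(
            np.maximum(np.abs(t0), scale) * rel_step)
        hstep = np.maximum(h, hstep)
        for i in range(m):
            for j in range(i, m):
                def f2(di, dj, i=i, j=j):
                    t = t0.copy()
                    t[i] = max(t[i] + di, 1e-12 * scale)
                    t[j] = max(t[j] + dj, 1e-12 * scale)
                    return ll_at(t)
                hess[i, j] = hess[j, i] = (
                    f2(hstep[i], hstep[j]) - f2(hstep[i], -hstep[j])
                    - f2(-hstep[i], hstep[j]) + f2(-hstep[i], -hstep[j])
                ) / (4.0 * hstep[i] * hstep[j])
        info = -hess
        df_resid = self._n - self._p
        try:
            denom = float(grad @ np.linalg.solve(info, grad))
            if denom <= 0:
                raise np.linalg.LinAlgError("non-positive delta-method variance")
            df2 = 2.0 * var_c ** 2 / denom
        except np.linalg.LinAlgError as exc:
            logger.warning("Satterthwaite information not invertible (%s); "
                           "falling back to residual df %d", exc, df_resid)
            df2 = float(df_resid)
        df2 = min(df2, float(df_resid))
        p = float(stats.f.sf(F, 1, df2))
        return {"F": float(F), "df1": 1, "df2": float(df2), "p": p,
                "estimate": float(est), "se": float(se)}


def fit_lmm(
    table: AnalysisTable | PhenotypeTable, trait: str, transform: str = "none",
    lrt_terms: bool = True, f_test: bool = True,
) -> VarianceComponents:
    """One Table-1-style row: REML fit + random-term LRTs + treatment F."""
    from .data import transform_trait

    src = table
    if transform != "none":
        if isinstance(table, AnalysisTable):
            raise ValueError("apply transforms on the raw PhenotypeTable")
        src = transform_trait(table, trait, transform)
    est = VarianceComponentsREML().fit(src.df if hasattr(src, "df") else src, trait)
    out = VarianceComponents(
        trait=trait, transform=transform,
        sigma2_g=est.sigma2_g_, sigma2_gxe=est.sigma2_gxe_, sigma2_e=est.sigma2_e_,
        fixed_effects=est.fixed_effects_, fixed_se=est.fixed_se_,
        loglik=est.loglik_, converged=est.converged_, grad_norm=est.grad_norm_,
        n_used=est.n_used_)
    if lrt_terms:
        out.chi2_g, out.p_g = est.lrt("genotype")
        out.chi2_gxe, out.p_gxe = est.lrt("gxe")
    if f_test:
        f = est.satterthwaite_f()
        out.f_treatment, out.df1, out.df2, out.p_treatment = (
            f["F"], f["df1"], f["df2"], f["p"])
    return out


def lrt_random_effect(model: VarianceComponentsREML, reduced_term: str,
                      boundary_mixture: bool = False) -> tuple[float, float]:
    """Functional wrapper: LRT chi^2 and p for dropping ``reduced_term``
    ('genotype' or 'gxe') from a fitted model."""
    return model.lrt(reduced_term, boundary_mixture=boundary_mixture)


def satterthwaite_f(model: VarianceComponentsREML) -> dict:
    """Functional wrapper for the Satterthwaite treatment F test."""
    return model.satterthwaite_f()


def variance_table(
    table: PhenotypeTable, traits_transforms: dict[str, str]
) -> pd.DataFrame:
    """Table-1-style summary over several traits.

    ``traits_transforms`` maps response column -> transform ('none'/'sqrt').
    Reports unrounded statistics alongside a 2-dp display column and
    significance stars at 0.05/0.01.
    """
    from .selection import significance_stars

    rows = []
    for trait, tf in traits_transforms.items():
        vc = fit_lmm(table, trait, transform=tf)
        rows.append({
            "trait": trait, "transform": tf,
            "sigma2_g": vc.sigma2_g, "sigma2_gxe": vc.sigma2_gxe,
            "sigma2_e": vc.sigma2_e,
            "chi2_genotype": vc.chi2_g, "p_genotype": vc.p_g,
            "stars_genotype": significance_stars(vc.p_g),
            "F_treatment": vc.f_treatment,
            "df_treatment": f"(1,{vc.df2:.0f})" if vc.df2 else "",
            "p_treatment": vc.p_treatment,
            "stars_treatment": significance_stars(vc.p_treatment),
            "chi2_gxe": vc.chi2_gxe, "p_gxe": vc.p_gxe,
            "stars_gxe": significance_stars(vc.p_gxe),
            "n_used": vc.n_used, "converged": vc.converged,
        })
    return pd.DataFrame(rows)
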