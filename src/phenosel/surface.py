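"""Nonparametric fitness landscapes: thin-plate spline smoothing with GCV.

A fitness surface over two standardized traits is estimated by penalized
thin-plate spline regression.  The fitted function is

    f(x) = d0 + d1 x1 + d2 x2 + sum_i c_i eta(|x - x_i|),
    eta(r) = r^2 log r,

where the affine part spans the unpenalized null space and the warp
coefficients c satisfy the side conditions P'c = 0 (orthogonality to the
null space), which together with

    (K + lambda W^-1) c + P d = y-bar,   P' c = 0

solve the penalized least-squares problem.  Duplicated trait coordinates are
collapsed to weighted pseudo-observations (weight = multiplicity, response =
within-location mean), which leaves the smoother trace and hence GCV
unchanged while keeping the kernel matrix nonsingular.

The smoothing parameter is chosen to minimize the generalized
cross-validation score GCV(lambda) = n RSS(lambda) / (n - tr A(lambda))^2,
searched on a log-spaced grid and refined by golden-section search.  As
lambda grows the fit shrinks toward the affine regression (effective df ->
3); as lambda -> 0 it interpolates distinct points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin


class DegenerateGeometryError(ValueError):
    """All design points are collinear; the TPS system is singular."""


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """eta(r) = r^2 log r, with eta(0) = 0."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _pairwise_eta(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(-1))
    return _tps_kernel(d)


@dataclass
class FitnessSurface:
    """A fitted two-trait fitness landscape."""

    trait_pair: tuple[str, str]
    knots: np.ndarray
    warp_coef: np.ndarray
    affine_coef: np.ndarray
    lam: float
    gcv: float
    edf: float
    n_used: int
    grid: pd.DataFrame | None = field(default=None, repr=False)
    grid_max: dict | None = None


class ThinPlateSpline(BaseEstimator, RegressorMixin):
    """Penalized thin-plate spline regressor in two dimensions.

    Parameters
    ----------
    lam
        Smoothing parameter >= 0, or ``"gcv"`` to minimize generalized
        cross-validation over ``n_lambdas`` log-spaced values in
        ``lambda_range`` (times a data-dependent scale) with golden-section
        refinement around the grid minimum.

    Attributes
    ----------
    lam_ : float
        The smoothing parameter actually used (GCV-selected if requested).
    edf_ : float
        Effective degrees of freedom tr A(lam).
    gcv_ : float
        GCV score at ``lam_``.
    """

    def __init__(self, lam: float | str = "gcv", n_lambdas: int = 40,
                 lambda_range: tuple[float, float] = (1e-8, 1e3)):
        self.lam = lam
        self.n_lambdas = n_lambdas
        self.lambda_range = lambda_range

    # -- core solver -------------------------------------------------------

    def _collapse(self, X: np.ndarray, y: np.ndarray):
        """Unique locations with multiplicity weights and mean responses."""
        uniq, inv, counts = np.unique(X, axis=0, return_inverse=True,
                                      return_counts=True)
        ybar = np.zeros(len(uniq))
        np.add.at(ybar, inv, y)
        ybar /= counts
        within_ss = float(((y - ybar[inv]) ** 2).sum())
        return uniq, counts.astype(float), ybar, inv, within_ss

    def _solve(self, lam: float):
        """Solve the bordered system at raw penalty ``lam``; returns
        (c, d, fitted_at_unique, trace of the n-point smoother, RSS)."""
        U, wts, ybar, inv, wss = self._Uc
        m = len(U)
        K = self._K
        P = self._P
        M = np.zeros((m + 3, m + 3))
        M[:m, :m] = K + lam * np.diag(1.0 / wts)
        M[:m, m:] = P
        M[m:, :m] = P.T
        rhs = np.zeros((m + 3, 1 + m))
        rhs[:m, 0] = ybar
        rhs[:m, 1:] = np.eye(m)
        try:
            sol = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as exc:
            raise DegenerateGeometryError(f"TPS system singular: {exc}") from exc
        c, d = sol[:m, 0], sol[m:, 0]
        F = K @ sol[:m, :] + P @ sol[m:, :]   # fitted map: col 0 = values
        fitted = F[:, 0]
        # smoother on collapsed data: A_c = F[:, 1:]; the n-point smoother
        # trace equals tr(A_c) because expansion/averaging are inverse maps
        # on the weighted space.
        trace = float(np.trace(F[:, 1:]))
        rss = wss + float((wts * (ybar - fitted) ** 2).sum())
        return c, d, fitted, trace, rss

    def _gcv_at(self, lam: float) -> tuple[float, float, float]:
        n = self._n_obs
        _, _, _, trace, rss = self._solve(lam)
        denom = n - trace
        if denom <= 0:
            return np.inf, trace, rss
        return n * rss / denom ** 2, trace, rss

    def fit(self, X, y) -> "ThinPlateSpline":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be n x 2 (two standardized traits)")
        if len(X) < 4:
            raise ValueError("need at least 4 points")
        self._Uc = self._collapse(X, y)
        U = self._Uc[0]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(U)), U])) < 3:
            raise DegenerateGeometryError("all design points are collinear")
        self._n_obs = len(y)
        self._K = _pairwise_eta(U, U)
        self._P = np.column_stack([np.ones(len(U)), U])
        # scale normalizing the penalty for n and coordinate spread
        self._lam_scale = float(np.abs(self._K).mean() + 1e-30)

        if isinstance(self.lam, str):
            if self.lam != "gcv":
                raise ValueError("lam must be a number or 'gcv'")
            lo, hi = self.lambda_range
            grid = np.logspace(np.log10(lo), np.log10(hi), self.n_lambdas)
            scores = np.array([self._gcv_at(g * self._lam_scale)[0] for g in grid])
            i = int(np.argmin(scores))
            a = grid[max(i - 1, 0)]
            b = grid[min(i + 1, len(grid) - 1)]
            if a < b:
                res = optimize.minimize_scalar(
                    lambda t: self._gcv_at(np.exp(t) * self._lam_scale)[0],
                    bounds=(np.log(a), np.log(b)), method="bounded",
                    options={"xatol": 1e-3})
                lam_rel = float(np.exp(res.x))
                if self._gcv_at(lam_rel * self._lam_scale)[0] > scores[i]:
                    lam_rel = float(grid[i])
            else:
                lam_rel = float(grid[i])
            lam = lam_rel * self._lam_scale
        else:
            if float(self.lam) < 0:
                raise ValueError("lam must be >= 0")
            # numeric lam is relative to the same data-dependent scale the
            # GCV grid uses, so lam values are comparable across datasets
            lam = float(self.lam) * self._lam_scale
        c, d, _, trace, rss = self._solve(lam)
        self.lam_ = lam
        self.warp_coef_ = c
        self.affine_coef_ = d
        self.edf_ = trace
        n = self._n_obs
        self.gcv_ = (n * rss / (n - trace) ** 2) if n > trace else np.inf
        self.knots_ = U
        self.n_used_ = n
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        E = _pairwise_eta(X, self.knots_)
        P = np.column_stack([np.ones(len(X)), X])
        return E @ self.warp_coef_ + P @ self.affine_coef_


def fit_tps(points: np.ndarray, w: np.ndarray, lam: float | str = "gcv",
            trait_pair: tuple[str, str] = ("trait_1", "trait_2")) -> FitnessSurface:
    """Fit a fitness surface over two standardized traits."""
    est = ThinPlateSpline(lam=lam).fit(points, w)
    surf = FitnessSurface(
        trait_pair=trait_pair, knots=est.knots_, warp_coef=est.warp_coef_,
        affine_coef=est.affine_coef_, lam=est.lam_, gcv=est.gcv_,
        edf=est.edf_, n_used=est.n_used_)
    surf._estimator = est
    return surf


def gcv_curve(points: np.ndarray, w: np.ndarray,
              lambdas: np.ndarray | None = None) -> pd.DataFrame:
    """GCV score and effective df across a smoothing-parameter grid.

    ``lambdas`` are relative to the data-dependent scale; default is the
    estimator's 40-point log grid.  Effective df decreases monotonically in
    lambda, from interpolation toward the 3-df affine floor.
    """
    est = ThinPlateSpline(lam=0.0).fit(points, w)
    if lambdas is None:
        lambdas = np.logspace(np.log10(est.lambda_range[0]),
                              np.log10(est.lambda_range[1]), est.n_lambdas)
    rows = []
    for lam_rel in np.asarray(lambdas, float):
        gcv, trace, rss = est._gcv_at(lam_rel * est._lam_scale)
        rows.append({"lambda": lam_rel, "gcv": gcv, "edf": trace, "rss": rss})
    return pd.DataFrame(rows)


def evaluate_grid(surface: FitnessSurface, resolution: int = 50,
                  extent: tuple[float, float, float, float] | None = None,
                  mask_hull: bool = True) -> FitnessSurface:
    """Evaluate the surface on a regular grid and locate its maximum.

    The default extent is the bounding box of the knots; with ``mask_hull``
    points outside the convex hull of the data are set to NaN, since a
    thin-plate spline extrapolates wildly outside data support.  Returns the
    surface with ``grid`` and ``grid_max`` filled in.
    """
    est = getattr(surface, "_estimator", None)
    if est is None:
        est = ThinPlateSpline(lam=surface.lam)
        est.knots_ = surface.knots
        est.warp_coef_ = surface.warp_coef
        est.affine_coef_ = surface.affine_coef
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    K = surface.knots
    if extent is None:
        extent = (K[:, 0].min(), K[:, 0].max(), K[:, 1].min(), K[:, 1].max())
    x0, x1, y0, y1 = extent
    if not (x1 >= x0 and y1 >= y0):
        raise ValueError(f"empty extent {extent}")
    if resolution == 1:
        xs = np.array([(x0 + x1) / 2.0])
        ys = np.array([(y0 + y1) / 2.0])
    else:
        xs = np.linspace(x0, x1, resolution)
        ys = np.linspace(y0, y1, resolution)
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    vals = est.predict(pts)
    if mask_hull and len(K) >= 3:
        inside = _in_hull(pts, K)
        vals = np.where(inside, vals, np.nan)
    grid = pd.DataFrame({surface.trait_pair[0]: pts[:, 0],
                         surface.trait_pair[1]: pts[:, 1],
                         "w_fit": vals})
    if np.isfinite(vals).any():
        imax = int(np.nanargmax(vals))
        surface.grid_max = {surface.trait_pair[0]: float(pts[imax, 0]),
                            surface.trait_pair[1]: float(pts[imax, 1]),
                            "w_fit": float(vals[imax])}
    surface.grid = grid
    return surface


def _in_hull(points: np.ndarray, hull_points: np.ndarray) -> np.ndarray:
    from scipy.spatial import Delaunay

    try:
        tri = Delaunay(hull_points)
    except Exception:
        return np.ones(len(points), bool)
    return tri.find_simplex(points) >= 0


def grid_local_maxima(surface: FitnessSurface, resolution: int | None = None
                      ) -> pd.DataFrame:
    """Interior local maxima of the evaluated grid (8-neighbour rule).

    Used to characterize surface shape, e.g. a negative correlational
    gradient producing two fitness peaks in opposite trait quadrants.
    """
    if surface.grid is None:
        raise ValueError("call evaluate_grid first")
    g = surface.grid
    xname, yname = surface.trait_pair
    xs = np.sort(g[xname].unique())
    ys = np.sort(g[yname].unique())
    V = g.pivot_table(index=yname, columns=xname, values="w_fit").to_numpy()
    rows = []
    for i in range(1, V.shape[0] - 1):
        for j in range(1, V.shape[1] - 1):
            v = V[i, j]
            if not np.isfinite(v):
                continue
            neigh = V[i - 1:i + 2, j - 1:j + 2].copy()
            neigh[1, 1] = -np.inf
            if v > np.nanmax(neigh):
                rows.append({xname: xs[j], yname: ys[i], "w_fit": v})
    return pd.DataFrame(rows, columns=[xname, yname, "w_fit"])


def plot_surface(surface: FitnessSurface, path=None, kind: str = "contour"):
    """Contour or perspective rendering of an evaluated surface."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if surface.grid is None:
        raise ValueError("call evaluate_grid first")
    g = surface.grid
    xname, yname = surface.trait_pair
    xs = np.sort(g[xname].unique())
    ys = np.sort(g[yname].unique())
    V = g.pivot_table(index=yname, columns=xname, values="w_fit").to_numpy()
    if kind == "perspective":
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        XX, YY = np.meshgrid(xs, ys)
        ax.plot_surface(XX, YY, V, cmap="RdYlBu_r")
        ax.set_zlabel("relative fitness")
    else:
        fig, ax = plt.subplots(figsize=(6, 5))
        cs = ax.contourf(xs, ys, V, levels=12, cmap="RdYlBu_r")
        ax.contour(xs, ys, V, levels=12, colors="k", linewidths=0.4)
        ax.plot(surface.knots[:, 0], surface.knots[:, 1], "^", ms=3, color="k")
        fig.colorbar(cs, ax=ax, label="relative fitness")
    ax.set_xlabel(xname)
    ax.set_ylabel(yname)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
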