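"""Log-polynomial point-process intensities as a cross-method comparison.

An alternative to the KDE score: each layer is modelled as an inhomogeneous
Poisson point process with log-polynomial intensity

    log lambda(x, y) = b0 + b1 x + b2 y + b3 x^2 + b4 x y + b5 y^2,

fitted by maximum likelihood via the Berman-Turner quadrature device —
the continuous Poisson likelihood is discretised onto quadrature points
(grid dummies plus the data points themselves) and maximised as a weighted
Poisson regression.  This is the first-order (trend) fit of a cluster
process; differencing the two fitted intensities after normalising each by
its total fitted mass yields a score surface on the same scale as the KDE
difference, for qualitative comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .kde_score import Grid, ScoreSurface, Window
from .preprocess import PlanarPoints

logger = logging.getLogger(__name__)


def _design(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(x)]
    if degree >= 1:
        cols += [x, y]
    if degree >= 2:
        cols += [x**2, x * y, y**2]
    return np.column_stack(cols)


@dataclass
class IntensityModel:
    """Fitted log-polynomial intensity over a rectangular window."""

    coefficients: np.ndarray  # length 1, 3 or 6 for degree 0, 1, 2
    degree: int
    window: Window
    loglik: float
    n: int

    def lambda_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        eta = _design(x.ravel(), y.ravel(), self.degree) @ self.coefficients
        return np.exp(eta).reshape(x.shape)

    def integral(self, n_cells: int = 200) -> float:
        """Riemann integral of the fitted intensity over the window (cell centers)."""
        w = self.window
        xs = w.x0 + w.width * (np.arange(n_cells) + 0.5) / n_cells
        ys = w.y0 + w.height * (np.arange(n_cells) + 0.5) / n_cells
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        cell = (w.width / n_cells) * (w.height / n_cells)
        return float(self.lambda_at(gx, gy).sum() * cell)


def fit_loglinear_intensity(
    points: PlanarPoints,
    window: Window,
    degree: int = 2,
    n_quad: int = 40,
) -> IntensityModel:
    """Maximum-likelihood fit of the log-polynomial intensity.

    Quadrature points are the cell centers of an ``n_quad`` x ``n_quad``
    partition of the window plus the data points; each quadrature point u
    carries the counting weight w_u = (cell area) / (points in its cell), and
    the weighted Poisson regression of y_u = 1{u is data}/w_u on the
    polynomial basis maximises the discretised Poisson log-likelihood
    sum_i log lambda(s_i) - integral_W lambda.  A degree-0 fit recovers the
    homogeneous MLE n/|W| exactly.
    """
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    n_coef = {0: 1, 1: 3, 2: 6}[degree]
    n = len(points)
    if n < 2 * n_coef:
        raise ValueError(f"need at least {2 * n_coef} points for degree {degree}")
    if not window.contains(points.x, points.y).all():
        raise ValueError("all points must lie inside the window")

    dx = window.width / n_quad
    dy = window.height / n_quad
    qx = window.x0 + dx * (np.arange(n_quad) + 0.5)
    qy = window.y0 + dy * (np.arange(n_quad) + 0.5)
    gx, gy = np.meshgrid(qx, qy, indexing="ij")
    ux = np.concatenate([gx.ravel(), points.x])
    uy = np.concatenate([gy.ravel(), points.y])
    is_data = np.zeros(len(ux))
    is_data[n_quad * n_quad:] = 1.0

    # counting weights: cell area shared among all quadrature points in the cell
    ci = np.clip(((ux - window.x0) / dx).astype(int), 0, n_quad - 1)
    cj = np.clip(((uy - window.y0) / dy).astype(int), 0, n_quad - 1)
    flat = ci * n_quad + cj
    per_cell = np.bincount(flat, minlength=n_quad * n_quad)
    w = (dx * dy) / per_cell[flat]

    X = _design(ux, uy, degree)
    y = is_data / w
    model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
    try:
        res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"intensity fit failed to converge: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("intensity fit produced non-finite coefficients")
    fitted = IntensityModel(
        coefficients=np.asarray(res.params),
        degree=degree,
        window=window,
        loglik=0.0,
        n=n,
    )
    loglik = float(
        np.sum(np.log(fitted.lambda_at(points.x, points.y))) - fitted.integral()
    )
    fitted.loglik = loglik
    return fitted


def incremental_intensity(
    pos_model: IntensityModel, neg_model: IntensityModel, grid: Grid
) -> ScoreSurface:
    """Mass-normalised intensity difference at the grid nodes.

    Each fitted intensity is divided by its own fitted total mass over the
    window, turning it into a density, so the difference is directly
    comparable to the KDE score surface.
    """
    if pos_model.window != neg_model.window:
        raise ValueError("intensity models fitted on different windows")
    xs, ys = grid.node_axes()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pos = pos_model.lambda_at(gx, gy) / pos_model.integral()
    neg = neg_model.lambda_at(gx, gy) / neg_model.integral()
    return ScoreSurface(grid=grid, values=pos - neg, layer="sors", h=float("nan"))
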