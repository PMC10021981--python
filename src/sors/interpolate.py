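"""Evaluating a gridded score surface at arbitrary interior locations.

Four methods mirror the interpolation scenario family: bilinear weights on
the enclosing cell (the base case), inverse-distance weighting over the four
enclosing nodes, nearest-node lookup, and ordinary kriging with a variogram
fitted to the node values by weighted least squares (nugget fixed at zero,
because node values are noise-free computed quantities — this keeps kriging
an exact interpolator).

Every method is linear in the node values, so it factors into a weight
vector over nodes that depends only on geometry (and, for kriging, the
variogram).  :func:`interp_node_weights` exposes that factorisation; the
scenario evaluation reuses one weight matrix across all bootstrap surfaces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

METHODS = ("bilinear", "idw", "nearest", "kriging")


@dataclass
class VariogramModel:
    """Isotropic semivariogram with zero nugget.

    exponential: gamma(d) = sill * (1 - exp(-d / range)) — ``range`` is the
    exponential scale parameter (covariance C(d) = sill * exp(-d / range)).
    spherical:   gamma(d) = sill * (1.5 u - 0.5 u^3) for u = d/range < 1,
    sill beyond.
    """

    model: str
    sill: float
    range: float
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("exponential", "spherical"):
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.sill <= 0 or self.range <= 0:
            raise ValueError("sill and range must be positive")
        if self.nugget != 0.0:
            raise ValueError("nugget is fixed at 0 (exact-interpolation contract)")

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.model == "exponential":
            return self.sill * (1.0 - np.exp(-d / self.range))
        u = np.minimum(d / self.range, 1.0)
        return self.sill * (1.5 * u - 0.5 * u**3)


# ---------------------------------------------------------------------------
# cell location helpers
# ---------------------------------------------------------------------------


def _axes(surface) -> tuple[np.ndarray, np.ndarray]:
    return surface.grid.node_axes()


def _check_hull(xs: np.ndarray, ys: np.ndarray, px: float, py: float) -> None:
    if not (xs[0] <= px <= xs[-1] and ys[0] <= py <= ys[-1]):
        raise ValueError(f"point ({px}, {py}) outside the grid-node hull")


def _cell_index(axis: np.ndarray, v: float) -> int:
    """Index i with axis[i] <= v <= axis[i+1], clamped to valid cells."""
    i = int(np.searchsorted(axis, v)) - 1
    return min(max(i, 0), len(axis) - 2)


def _corner_nodes(xs, ys, px, py):
    i = _cell_index(xs, px)
    j = _cell_index(ys, py)
    corners = [(i, j), (i + 1, j), (i, j + 1), (i + 1, j + 1)]
    return i, j, corners


# ---------------------------------------------------------------------------
# the four methods (scalar API)
# ---------------------------------------------------------------------------


def interp_bilinear(surface, p: tuple[float, float]) -> float:
    """Bilinear interpolation on the enclosing grid cell (reproduces affine surfaces)."""
    xs, ys = _axes(surface)
    px, py = p
    _check_hull(xs, ys, px, py)
    i, j, _ = _corner_nodes(xs, ys, px, py)
    t = (px - xs[i]) / (xs[i + 1] - xs[i])
    u = (py - ys[j]) / (ys[j + 1] - ys[j])
    v = surface.values
    return float(
        (1 - t) * (1 - u) * v[i, j]
        + t * (1 - u) * v[i + 1, j]
        + (1 - t) * u * v[i, j + 1]
        + t * u * v[i + 1, j + 1]
    )


def interp_idw4(surface, p: tuple[float, float], power: float = 2.0) -> float:
    """Inverse-distance weighting over the four enclosing nodes (Shepard power 2)."""
    xs, ys = _axes(surface)
    px, py = p
    _check_hull(xs, ys, px, py)
    _, _, corners = _corner_nodes(xs, ys, px, py)
    num = 0.0
    den = 0.0
    for ci, cj in corners:
        d = np.hypot(px - xs[ci], py - ys[cj])
        if d == 0.0:
            return float(surface.values[ci, cj])
        w = d ** (-power)
        num += w * surface.values[ci, cj]
        den += w
    return float(num / den)


def interp_nearest(surface, p: tuple[float, float]) -> float:
    """Value at the nearest node; ties broken toward the lower (row, column) index."""
    xs, ys = _axes(surface)
    px, py = p
    _check_hull(xs, ys, px, py)
    # per-axis nearest with ties to the lower index gives the lexicographic rule
    di = np.abs(xs - px)
    dj = np.abs(ys - py)
    return float(surface.values[int(np.argmin(di)), int(np.argmin(dj))])


def fit_variogram(
    surface,
    n_bins: int = 15,
    max_nodes: int = 1500,
    seed: int = 0,
    model: str | None = None,
) -> VariogramModel:
    """Fit a zero-nugget variogram to the surface's node values by WLS.

    Empirical semivariances gamma(d) = mean of (v_i - v_j)^2 / 2 are binned
    over node-pair distances up to half the window diagonal; exponential and
    spherical models are fitted by least squares weighted with sqrt(pair
    count), and the better-fitting model wins (exponential on ties) unless
    ``model`` pins one family.  Grids larger than ``max_nodes`` nodes are
    subsampled deterministically.
    """
    coords = surface.grid.node_coords()
    vals = surface.values.ravel()
    if len(vals) < 10:
        raise ValueError("need at least 10 nodes to fit a variogram")
    if len(vals) > max_nodes:
        idx = np.random.default_rng(seed).choice(len(vals), size=max_nodes, replace=False)
        coords, vals = coords[idx], vals[idx]
    d = pdist(coords)
    g = pdist(vals[:, None], metric="sqeuclidean") / 2.0
    # restrict to short lags: the single-realization empirical variogram is
    # unreliable at distances comparable to the window, inflating the range
    dmax = 0.35 * np.hypot(
        surface.grid.window.width, surface.grid.window.height
    )
    keep = d <= dmax
    d, g = d[keep], g[keep]
    edges = np.linspace(0.0, dmax, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    ok = counts > 0
    gamma_hat = np.bincount(which, weights=g, minlength=n_bins)[ok] / counts[ok]
    centers = (0.5 * (edges[:-1] + edges[1:]))[ok]
    wts = np.sqrt(counts[ok])

    def fit_one(model: str) -> tuple[VariogramModel, float]:
        def resid(theta):
            vm = VariogramModel(model=model, sill=theta[0], range=theta[1])
            return wts * (vm(centers) - gamma_hat)

        gmax = max(gamma_hat.max(), 1e-12)
        x0 = [gmax, dmax / 3.0]
        sol = least_squares(
            resid,
            x0,
            bounds=([1e-12, dmax / 100.0], [10.0 * gmax, 5.0 * dmax]),
            method="trf",
            max_nfev=2000,
        )
        vm = VariogramModel(model=model, sill=sol.x[0], range=sol.x[1])
        return vm, float(np.sum(sol.fun**2))

    if model is not None:
        return fit_one(model)[0]
    best_vm, best_sse = fit_one("exponential")
    sph_vm, sph_sse = fit_one("spherical")
    if sph_sse < best_sse:
        best_vm = sph_vm
    return best_vm


def interp_kriging(
    surface,
    p: tuple[float, float],
    model: VariogramModel,
    k_neighbors: int = 64,
) -> float:
    """Ordinary kriging prediction from the k nearest grid nodes.

    Solves the standard OK system in semivariance form with a Lagrange
    multiplier enforcing unit weight sum; with zero nugget the prediction at
    a node equals the node value.  A singular system falls back to bilinear
    interpolation with a warning.
    """
    xs, ys = _axes(surface)
    _check_hull(xs, ys, p[0], p[1])
    idx, w = _kriging_weights(surface.grid, np.atleast_2d(p), model, k_neighbors)
    if idx is None:
        warnings.warn("singular kriging system; falling back to bilinear", stacklevel=2)
        return interp_bilinear(surface, p)
    return float(surface.values.ravel()[idx[0]] @ w[0])


def _kriging_weights(grid, pts: np.ndarray, model: VariogramModel, k: int):
    """OK weights for each row of pts; returns (indices (N,k), weights (N,k)) or (None, None)."""
    coords = grid.node_coords()
    k = min(k, len(coords))
    tree = cKDTree(coords)
    _, nn = tree.query(pts, k=k)
    nn = np.atleast_2d(nn)
    all_idx = np.empty((len(pts), k), dtype=int)
    all_w = np.empty((len(pts), k))
    for row, (pt, neigh) in enumerate(zip(pts, nn)):
        sub = coords[neigh]
        gamma_nn = model(squareform(pdist(sub), checks=False))
        a = np.empty((k + 1, k + 1))
        a[:k, :k] = gamma_nn
        a[k, :] = 1.0
        a[:, k] = 1.0
        a[k, k] = 0.0
        b = np.empty(k + 1)
        b[:k] = model(np.hypot(sub[:, 0] - pt[0], sub[:, 1] - pt[1]))
        b[k] = 1.0
        try:
            lam = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            return None, None
        all_idx[row] = neigh
        all_w[row] = lam[:k]
    return all_idx, all_w


# ---------------------------------------------------------------------------
# batch weight-matrix API (reused across bootstrap replicates)
# ---------------------------------------------------------------------------


def interp_node_weights(
    grid,
    pts: np.ndarray,
    method: str,
    power: float = 2.0,
    variogram: VariogramModel | None = None,
    k_neighbors: int = 64,
) -> sparse.csr_matrix:
    """Sparse (n_points, nx*ny) weight matrix W with prediction = W @ values.ravel().

    Node values are raveled in C order over the (nx, ny) value array.  All
    four methods are linear in node values, so interpolating B bootstrap
    surfaces at N points is a single sparse product per surface.
    """
    if method not in METHODS:
        raise ValueError(f"unknown interpolation method {method!r}")
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    xs, ys = grid.node_axes()
    ny = grid.ny
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []

    if method == "kriging":
        if variogram is None:
            raise ValueError("kriging needs a fitted variogram")
        for px, py in pts:
            _check_hull(xs, ys, px, py)
        idx, w = _kriging_weights(grid, pts, variogram, k_neighbors)
        if idx is None:
            warnings.warn("singular kriging system; falling back to bilinear", stacklevel=2)
            return interp_node_weights(grid, pts, "bilinear")
        for row in range(len(pts)):
            rows.extend([row] * idx.shape[1])
            cols.extend(idx[row])
            data.extend(w[row])
    else:
        for row, (px, py) in enumerate(pts):
            _check_hull(xs, ys, px, py)
            if method == "nearest":
                i = int(np.argmin(np.abs(xs - px)))
                j = int(np.argmin(np.abs(ys - py)))
                rows.append(row)
                cols.append(i * ny + j)
                data.append(1.0)
                continue
            i, j, corners = _corner_nodes(xs, ys, px, py)
            if method == "bilinear":
                t = (px - xs[i]) / (xs[i + 1] - xs[i])
                u = (py - ys[j]) / (ys[j + 1] - ys[j])
                wts = [(1 - t) * (1 - u), t * (1 - u), (1 - t) * u, t * u]
            else:  # idw
                dists = [np.hypot(px - xs[ci], py - ys[cj]) for ci, cj in corners]
                if min(dists) == 0.0:
                    wts = [1.0 if d == 0.0 else 0.0 for d in dists]
                else:
                    raw = [d ** (-power) for d in dists]
                    s = sum(raw)
                    wts = [r / s for r in raw]
            for (ci, cj), wt in zip(corners, wts):
                rows.append(row)
                cols.append(ci * ny + cj)
                data.append(float(wt))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(pts), grid.nx * grid.ny)
    )
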