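"""Observation window, grid, oversmoothing bandwidth and the score surface.

The risk score is the nodewise difference of two weighted Gaussian kernel
density surfaces, one per POI layer, computed on a shared grid over an
enlarged observation window:

* the "exact box" is the minimum axis-aligned bounding rectangle of the
  study boundary;
* the observation window scales each side of the exact box by an expansion
  factor (base case 1.4), concentrically — the enlargement is the edge
  correction: border densities are fed by mass outside the boundary;
* the grid places 25 nodes per dimension on the exact box and 10 more per
  +0.4 of expansion factor, at CELL CENTERS.  With nx = 25 + 10k on a window
  of width (1 + 0.4k)·W the spacing is (1 + 0.4k)·W / (25 + 10k) = W/25 for
  every k, and the node lattice of step k+1 contains the lattice of step k
  shifted by exactly 5 whole cells — so interior node locations and spacing
  are preserved across the edge-correction scenarios.  An endpoint lattice
  has neither property, which is why cell centers are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geodata_io import BoundaryPolygon
from .preprocess import PlanarPoints

#: Expansion factors of the edge-correction scenario family (base case 1.4).
EXPANSION_FACTORS = (1.0, 1.4, 1.8, 2.2, 2.6, 3.0)

# Terrell's maximal-smoothing constant for the bivariate (d = 2) Gaussian
# kernel.  The oversmoothing principle gives
#   h_OS = sigma * [ R(K) (d+8)^((d+6)/2) pi^(d/2)
#                    / (16 n Gamma((d+8)/2) d (d+2)) ]^(1/(d+4))
# with kernel roughness R(K) = (4 pi)^(-d/2).  For d = 2:
#   numerator   = 10^4 * pi * (4 pi)^(-1) = 2500
#   denominator = 16 * Gamma(5) * 2 * 4   = 3072
# so h_OS = sigma * (2500 / 3072)^(1/6) * n^(-1/6).
TERRELL_C2 = (2500.0 / 3072.0) ** (1.0 / 6.0)


@dataclass(frozen=True)
class Window:
    """Axis-aligned observation rectangle in planar units."""

    x0: float
    x1: float
    y0: float
    y1: float
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("window must have positive extent")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


@dataclass(frozen=True)
class Grid:
    """Cell-center lattice of an nx x ny partition of a window."""

    window: Window
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 nodes per dimension")

    @property
    def spacing(self) -> tuple[float, float]:
        return (self.window.width / self.nx, self.window.height / self.ny)

    def node_axes(self) -> tuple[np.ndarray, np.ndarray]:
        dx, dy = self.spacing
        xs = self.window.x0 + dx * (np.arange(self.nx) + 0.5)
        ys = self.window.y0 + dy * (np.arange(self.ny) + 0.5)
        return xs, ys

    def node_coords(self) -> np.ndarray:
        """All node coordinates, shape (nx*ny, 2), x varying fastest."""
        xs, ys = self.node_axes()
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class Bandwidth:
    """Kernel standard deviation in planar units with its provenance."""

    h: float
    n_pooled: int
    sigma_pooled: float
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("bandwidth must be positive")

    def scaled(self, multiplier: float) -> "Bandwidth":
        return Bandwidth(
            h=self.h / self.multiplier * multiplier,
            n_pooled=self.n_pooled,
            sigma_pooled=self.sigma_pooled,
            multiplier=multiplier,
        )


@dataclass
class DensitySurface:
    """Weighted KDE values at the grid nodes; integrates to 1 over the plane."""

    grid: Grid
    values: np.ndarray  # shape (nx, ny)
    layer: str
    h: float
    total_weight: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nx, self.grid.ny):
            raise ValueError("values shape does not match grid")

    def window_integral(self) -> float:
        """Trapezoid-free Riemann integral over the window (nodes are cell centers)."""
        dx, dy = self.grid.spacing
        return float(self.values.sum() * dx * dy)


@dataclass
class ScoreSurface(DensitySurface):
    """Obesogenic minus protective density; positive values mean higher risk."""


def exact_box(boundary: BoundaryPolygon) -> Window:
    """Minimum axis-aligned bounding rectangle of the study boundary."""
    x0, y0, x1, y1 = boundary.polygon.bounds
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate boundary")
    return Window(x0=x0, x1=x1, y0=y0, y1=y1, expansion_factor=1.0)


def expand_window(w: Window, factor: float) -> Window:
    """Scale each side length by ``factor`` about the window center."""
    if factor < 1:
        raise ValueError("expansion factor must be >= 1")
    cx, cy = w.center
    hw, hh = 0.5 * factor * w.width, 0.5 * factor * w.height
    return Window(
        x0=cx - hw,
        x1=cx + hw,
        y0=cy - hh,
        y1=cy + hh,
        expansion_factor=w.expansion_factor * factor,
    )


def grid_for(exact: Window, factor: float, override_n: int | None = None) -> Grid:
    """Build the cell-center grid on the window expanded by ``factor``.

    Without ``override_n`` the node count follows the +10-per-0.4 rule
    (25 at factor 1, 35 at the 1.4 base case, ...), which keeps spacing and
    interior node positions identical across expansion factors.  The
    grid-point scenarios pass ``override_n`` (70, 105) at factor 1.4 instead.
    """
    window = expand_window(exact, factor)
    if override_n is not None:
        n = int(override_n)
    else:
        k = (factor - 1.0) / 0.4
        if abs(k - round(k)) > 1e-9 or round(k) < 0:
            raise ValueError(
                f"factor {factor} is not 1 + 0.4k; pass override_n for custom grids"
            )
        n = 25 + 10 * int(round(k))
    return Grid(window=window, nx=n, ny=n)


def pooled_os_bandwidth(pos: PlanarPoints, neg: PlanarPoints) -> Bandwidth:
    """Terrell oversmoothing bandwidth on the union of both layers.

    A single bandwidth computed on the pooled point set is used for both
    density surfaces, so the difference surface compares like with like.
    The pooled dispersion is sigma = sqrt((s_x^2 + s_y^2) / 2) and
    h = TERRELL_C2 * sigma * n^(-1/6).
    """
    x = np.concatenate([pos.x, neg.x])
    y = np.concatenate([pos.y, neg.y])
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pooled points")
    sigma = math.sqrt(0.5 * (np.var(x, ddof=1) + np.var(y, ddof=1)))
    if sigma <= 0:
        raise ValueError("zero dispersion in pooled points")
    h = TERRELL_C2 * sigma * n ** (-1.0 / 6.0)
    return Bandwidth(h=h, n_pooled=n, sigma_pooled=sigma, multiplier=1.0)


def kde_surface(points: PlanarPoints, h: Bandwidth | float, grid: Grid) -> DensitySurface:
    """Weighted isotropic-Gaussian KDE of one layer evaluated at the grid nodes.

    f(s) = sum_i w_i phi_h(s - s_i) / sum_i w_i, with phi_h the bivariate
    normal density of standard deviation h in each coordinate.  Weights only
    reweight the mixture; the surface always integrates to one over the plane.
    """
    h_val = h.h if isinstance(h, Bandwidth) else float(h)
    if h_val <= 0:
        raise ValueError("bandwidth must be positive")
    if len(points) == 0:
        raise ValueError("empty point layer")
    xs, ys = grid.node_axes()
    # separable kernel: G[i, k] = exp(-(xs_i - x_k)^2 / 2h^2) etc., then
    # values = (Gx * w) @ Gy^T keeps the cost at O((nx + ny) n) exps
    gx = np.exp(-0.5 * ((xs[:, None] - points.x[None, :]) / h_val) ** 2)
    gy = np.exp(-0.5 * ((ys[:, None] - points.y[None, :]) / h_val) ** 2)
    w = points.weights
    values = (gx * w[None, :]) @ gy.T
    values /= 2.0 * math.pi * h_val**2 * w.sum()
    layer = str(points.layer[0]) if len(points) else "unknown"
    return DensitySurface(
        grid=grid, values=values, layer=layer, h=h_val, total_weight=float(w.sum())
    )


def sors_surface(pos: DensitySurface, neg: DensitySurface) -> ScoreSurface:
    """Difference surface: obesogenic density minus protective density."""
    if pos.grid != neg.grid:
        raise ValueError("surfaces live on different grids")
    if not math.isclose(pos.h, neg.h, rel_tol=1e-12):
        raise ValueError("surfaces built with different bandwidths")
    return ScoreSurface(
        grid=pos.grid,
        values=pos.values - neg.values,
        layer="sors",
        h=pos.h,
        total_weight=pos.total_weight + neg.total_weight,
    )
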