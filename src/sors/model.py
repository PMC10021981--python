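"""Model/Results front end tying the pipeline together.

:class:`SORSModel` holds a planar POI set and its study boundary together
with the scoring settings (expansion factor, grid size, bandwidth
multiplier, weighting scheme); :meth:`SORSModel.fit` builds the two density
surfaces and their difference and returns a :class:`SORSResults` carrying
the surfaces, the bandwidth and prediction/diagnostic methods.

:class:`SensitivityAnalysis` wraps the scenario grid, the fixed spatial
bootstrap and the ANOVA evaluation; :meth:`SensitivityAnalysis.run` returns
a :class:`SensitivityResults` with the per-scenario F table and the
per-parameter relative influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import (
    FTable,
    StudyData,
    draw_bootstrap,
    relative_influence,
    run_all_scenarios,
    sample_evaluation_points,
)
from .geodata_io import BoundaryPolygon, CategoryMapping, default_category_mapping, read_boundary, read_poi_collection
from .interpolate import METHODS, fit_variogram, interp_node_weights
from .kde_score import (
    Bandwidth,
    DensitySurface,
    Grid,
    ScoreSurface,
    exact_box,
    grid_for,
    kde_surface,
    pooled_os_bandwidth,
    sors_surface,
)
from .preprocess import (
    PlanarPoints,
    WeightingScheme,
    assign_weights,
    equidistant_transform,
    reduce_bus_stops,
)
from .ripley import KEstimate, clustering_verdict, loh_bands


class SORSModel:
    """Spatial obesity risk score model over a categorized planar POI set.

    Parameters
    ----------
    points : PlanarPoints
        Categorized POIs in the equidistant planar frame (both layers).
    boundary : BoundaryPolygon
        Planar study-area boundary; its bounding box is the exact box.
    expansion_factor : float
        Side-length multiplier of the observation window (edge correction).
    grid_n : int, optional
        Nodes per grid dimension; default follows the +10-per-0.4 rule.
    bandwidth_multiplier : float
        Scale applied to the Terrell oversmoothing bandwidth.
    weighting : str
        'equal', 'double_supermarket_gym' or 'custom'.
    """

    def __init__(
        self,
        points: PlanarPoints,
        boundary: BoundaryPolygon,
        expansion_factor: float = 1.4,
        grid_n: int | None = None,
        bandwidth_multiplier: float = 1.0,
        weighting: str | WeightingScheme = "equal",
    ) -> None:
        if boundary.crs_state != "planar":
            raise ValueError("boundary must be planar; use from_geojson for raw files")
        self.scheme = weighting if isinstance(weighting, WeightingScheme) else WeightingScheme(name=weighting)
        self.points = assign_weights(points, self.scheme)
        self.boundary = boundary
        self.expansion_factor = expansion_factor
        self.grid_n = grid_n
        self.bandwidth_multiplier = bandwidth_multiplier
        self.exact_box = exact_box(boundary)
        self.grid: Grid = grid_for(self.exact_box, expansion_factor, override_n=grid_n)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_geojson(
        cls,
        poi_path: str | Path,
        boundary_path: str | Path,
        mapping: CategoryMapping | None = None,
        reduce_bus: bool = True,
        bus_eps: float = 0.004,
        bus_min_pts: int = 3,
        **kwargs,
    ) -> "SORSModel":
        """Read raw geographic files, transform to planar, optionally reduce bus stops."""
        mapping = mapping or default_category_mapping()
        records = read_poi_collection(poi_path, mapping)
        boundary = read_boundary(boundary_path)
        points, planar_boundary = equidistant_transform(records, boundary)
        if reduce_bus:
            points = reduce_bus_stops(points, eps=bus_eps, min_pts=bus_min_pts)
        return cls(points, planar_boundary, **kwargs)

    @property
    def data(self) -> StudyData:
        return StudyData(points=self.points, boundary=self.boundary)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "SORSResults":
        pos = self.points.select_layer("obesogenic")
        neg = self.points.select_layer("protective")
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("both layers must be non-empty")
        bandwidth = pooled_os_bandwidth(pos, neg).scaled(self.bandwidth_multiplier)
        pos_surface = kde_surface(pos, bandwidth, self.grid)
        neg_surface = kde_surface(neg, bandwidth, self.grid)
        score = sors_surface(pos_surface, neg_surface)
        return SORSResults(
            model=self,
            bandwidth=bandwidth,
            pos_surface=pos_surface,
            neg_surface=neg_surface,
            score_surface=score,
        )


@dataclass
class SORSResults:
    """Fitted score surface with its provenance and prediction methods."""

    model: SORSModel
    bandwidth: Bandwidth
    pos_surface: DensitySurface
    neg_surface: DensitySurface
    score_surface: ScoreSurface

    def predict(self, points: np.ndarray, method: str = "bilinear") -> np.ndarray:
        """Score at arbitrary interior locations via one of the four interpolators."""
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        variogram = fit_variogram(self.score_surface) if method == "kriging" else None
        w = interp_node_weights(self.score_surface.grid, pts, method, variogram=variogram)
        return w @ self.score_surface.values.ravel()

    def ripley(
        self, layer: str, B: int = 1000, alpha: float = 0.05, seed: int = 0
    ) -> tuple[KEstimate, str]:
        """K function of one (unweighted) layer on the observation window, with bands."""
        pts = self.model.points.select_layer(layer)
        window = self.score_surface.grid.window
        inside = window.contains(pts.x, pts.y)
        if not inside.all():
            pts = pts.subset(np.flatnonzero(inside))
        kest = loh_bands(pts, window, B=B, alpha=alpha, seed=seed)
        _, overall = clustering_verdict(kest)
        return kest, overall

    def summary(self) -> str:
        m = self.model
        pos_n = int((m.points.layer == "obesogenic").sum())
        neg_n = int((m.points.layer == "protective").sum())
        v = self.score_surface.values
        lines = [
            "Spatial Obesity Risk Score",
            "==========================",
            f"POIs: {pos_n} obesogenic, {neg_n} protective",
            f"Observation window: expansion factor {m.expansion_factor:g}, "
            f"grid {m.grid.nx} x {m.grid.ny}",
            f"Bandwidth: h = {self.bandwidth.h:.6g} planar units "
            f"(Terrell x {self.bandwidth.multiplier:g}, pooled n = {self.bandwidth.n_pooled}, "
            f"sigma = {self.bandwidth.sigma_pooled:.6g})",
            f"Weighting: {m.scheme.name}",
            f"Score range: [{v.min():.6g}, {v.max():.6g}]  "
            f"(positive = obesogenic dominance)",
            f"Density window integrals: obesogenic {self.pos_surface.window_integral():.4f}, "
            f"protective {self.neg_surface.window_integral():.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, cmap: str = "RdBu_r"):
        """Heat map of the score surface with the boundary overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.score_surface.grid
        vmax = np.abs(self.score_surface.values).max()
        im = ax.imshow(
            self.score_surface.values.T,
            origin="lower",
            extent=(g.window.x0, g.window.x1, g.window.y0, g.window.y1),
            cmap=cmap,
            vmin=-vmax,
            vmax=vmax,
        )
        bx, by = self.model.boundary.polygon.exterior.xy
        ax.plot(bx, by, color="black", lw=1)
        ax.set_xlabel("x (planar units)")
        ax.set_ylabel("y (planar units)")
        plt.colorbar(im, ax=ax, label="risk score")
        return ax


class SensitivityAnalysis:
    """Scenario grid + spatial bootstrap + ANOVA around a model's data."""

    def __init__(
        self,
        model: SORSModel,
        n_eps: int = 50,
        B: int = 1000,
        seed: int = 0,
        area: str = "study area",
        recompute_bandwidth: bool = True,
    ) -> None:
        self.model = model
        self.n_eps = n_eps
        self.B = B
        self.seed = seed
        self.area = area
        self.recompute_bandwidth = recompute_bandwidth

    def run(self) -> "SensitivityResults":
        data = self.model.data
        eps = sample_evaluation_points(data.boundary, N=self.n_eps, seed=self.seed)
        pos_n = int((data.points.layer == "obesogenic").sum())
        neg_n = int((data.points.layer == "protective").sum())
        boots = draw_bootstrap(pos_n, neg_n, B=self.B, seed=self.seed + 1)
        ftable = run_all_scenarios(
            data, eps, boots, area=self.area, recompute_bandwidth=self.recompute_bandwidth
        )
        return SensitivityResults(
            ftable=ftable,
            influence=relative_influence(ftable),
            eps=eps,
            seed=self.seed,
            B=self.B,
        )


@dataclass
class SensitivityResults:
    ftable: FTable
    influence: dict[str, float]
    eps: np.ndarray
    seed: int
    B: int
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame(
                [
                    {
                        "area": r.area,
                        "scenario": r.scenario_id,
                        "parameter": r.parameter,
                        "F": r.f_value,
                    }
                    for r in self.ftable.rows
                ]
            )
        return self._frame

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Scenario sensitivity (one-way ANOVA F, higher = sharper discrimination)",
            "=" * 71,
            df.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
            "",
            f"Evaluation points: {len(self.eps)}; bootstrap replicates: {self.B}; seed: {self.seed}",
            "",
            "Relative influence per parameter family ((max F - min F) / base F):",
        ]
        for fam, infl in sorted(self.influence.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {fam:<16s} {infl:.3f}")
        return "\n".join(lines)
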