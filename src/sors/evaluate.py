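"""Scenario grid, fixed spatial bootstrap, and ANOVA-based score evaluation.

The sensitivity design varies one KDE parameter at a time around a base case
of (Terrell bandwidth x 1, expansion factor 1.4, 35 x 35 grid, bilinear
interpolation, equal weights), giving 19 labelled scenarios in five families:
bandwidth (BW1-BW5), edge correction (EC1-EC5), grid points (GP1-GP3),
interpolation (INT1-INT4) and weighting (WT1-WT2); the base case re-appears
in every family under its family-local label.

Uncertainty in the POI locations is propagated by a spatial bootstrap:
with-replacement resamples of each layer, drawn ONCE and reused for every
scenario so scenario-to-scenario differences in the resulting F statistics
reflect settings only.  For each scenario, both density surfaces are rebuilt
per resample (the bandwidth is recomputed on the resample and then scaled by
the scenario multiplier), the score surface is interpolated at N fixed
evaluation points, and the N x B score matrix is condensed into a one-way
ANOVA F statistic: between-evaluation-point variance over within-point
(bootstrap) variance.  Higher F means the score separates low- from
high-risk locations more sharply than its own sampling noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point

from .geodata_io import BoundaryPolygon
from .interpolate import VariogramModel, fit_variogram, interp_node_weights
from .kde_score import (
    Grid,
    exact_box,
    grid_for,
    kde_surface,
    pooled_os_bandwidth,
    sors_surface,
)
from .preprocess import PlanarPoints, WeightingScheme, assign_weights

logger = logging.getLogger(__name__)

BASE_BANDWIDTH_MULT = 1.0
BASE_FACTOR = 1.4
BASE_GRID_N = 35
BASE_INTERP = "bilinear"
BASE_WEIGHTING = "equal"


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the sensitivity grid, all non-varied settings at base case."""

    parameter: str  # bandwidth | edge_correction | grid_points | interpolation | weighting
    level_id: str  # e.g. BW1, EC3, INT4
    bandwidth_multiplier: float = BASE_BANDWIDTH_MULT
    expansion_factor: float = BASE_FACTOR
    grid_n: int | None = None  # None -> the +10-per-0.4 rule for the factor
    interp_method: str = BASE_INTERP
    weighting: str = BASE_WEIGHTING

    @property
    def is_base_case(self) -> bool:
        return (
            self.bandwidth_multiplier == BASE_BANDWIDTH_MULT
            and self.expansion_factor == BASE_FACTOR
            and self.grid_n in (None, BASE_GRID_N)
            and self.interp_method == BASE_INTERP
            and self.weighting == BASE_WEIGHTING
        )


def table2_scenarios() -> list[ScenarioSpec]:
    """The 19 labelled scenarios of the sensitivity design."""
    out: list[ScenarioSpec] = []
    for i, mult in enumerate([1 / 3, 2 / 3, 1.0, 4 / 3, 5 / 3], start=1):
        out.append(
            ScenarioSpec("bandwidth", f"BW{i}", bandwidth_multiplier=mult)
        )
    for i, factor in enumerate([1.4, 1.8, 2.2, 2.6, 3.0], start=1):
        out.append(
            ScenarioSpec("edge_correction", f"EC{i}", expansion_factor=factor)
        )
    for i, n in enumerate([35, 70, 105], start=1):
        out.append(ScenarioSpec("grid_points", f"GP{i}", grid_n=n))
    for i, meth in enumerate(["bilinear", "idw", "nearest", "kriging"], start=1):
        out.append(ScenarioSpec("interpolation", f"INT{i}", interp_method=meth))
    for i, wt in enumerate(["equal", "double_supermarket_gym"], start=1):
        out.append(ScenarioSpec("weighting", f"WT{i}", weighting=wt))
    return out


@dataclass
class BootstrapSet:
    """With-replacement index resamples per layer, fixed across scenarios."""

    pos_idx: np.ndarray  # (B, n_pos)
    neg_idx: np.ndarray  # (B, n_neg)
    seed: int

    @property
    def B(self) -> int:
        return self.pos_idx.shape[0]


@dataclass
class ScoreMatrix:
    """Scores at N evaluation points (rows) across B bootstrap replicates (columns)."""

    values: np.ndarray
    scenario_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix contains non-finite values")


@dataclass
class FRow:
    area: str
    scenario_id: str
    parameter: str
    f_value: float


@dataclass
class FTable:
    rows: list[FRow] = field(default_factory=list)

    def by_family(self) -> dict[str, list[FRow]]:
        fam: dict[str, list[FRow]] = {}
        for row in self.rows:
            fam.setdefault(row.parameter, []).append(row)
        return fam

    def f_of(self, scenario_id: str) -> float:
        for row in self.rows:
            if row.scenario_id == scenario_id:
                return row.f_value
        raise KeyError(scenario_id)


@dataclass
class StudyData:
    """Planar POI set plus the planar study boundary it belongs to."""

    points: PlanarPoints
    boundary: BoundaryPolygon

    def __post_init__(self) -> None:
        if self.boundary.crs_state != "planar":
            raise ValueError("boundary must be planar; run equidistant_transform first")


def sample_evaluation_points(
    boundary: BoundaryPolygon, N: int = 50, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """N points uniform over the boundary polygon by rejection from its bbox."""
    if N < 2:
        raise ValueError("need at least 2 evaluation points")
    poly = boundary.polygon
    if poly.area <= 0:
        raise ValueError("boundary has zero area")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0, y0, x1, y1 = poly.bounds
    pts: list[tuple[float, float]] = []
    while len(pts) < N:
        cand = rng.uniform([x0, y0], [x1, y1], size=(max(4 * N, 64), 2))
        for cx, cy in cand:
            if poly.contains(Point(cx, cy)):
                pts.append((cx, cy))
                if len(pts) == N:
                    break
    return np.asarray(pts)


def draw_bootstrap(
    n_pos: int, n_neg: int, B: int = 1000, seed: int = 0
) -> BootstrapSet:
    """Draw the fixed bootstrap index set: B resamples per layer, sizes preserved."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both layers must be non-empty")
    rng = np.random.default_rng(seed)
    return BootstrapSet(
        pos_idx=rng.integers(0, n_pos, size=(B, n_pos)),
        neg_idx=rng.integers(0, n_neg, size=(B, n_neg)),
        seed=seed,
    )


def _resolve_grid(data: StudyData, spec: ScenarioSpec) -> Grid:
    box = exact_box(data.boundary)
    return grid_for(box, spec.expansion_factor, override_n=spec.grid_n)


def _scheme_for(name: str) -> WeightingScheme:
    return WeightingScheme(name=name)


def _build_score_values(
    pos: PlanarPoints,
    neg: PlanarPoints,
    grid: Grid,
    bandwidth_multiplier: float,
    freeze_h: float | None = None,
) -> np.ndarray:
    """Raveled score-surface node values for one (possibly resampled) point set."""
    if freeze_h is None:
        h = pooled_os_bandwidth(pos, neg).scaled(bandwidth_multiplier)
    else:
        h = freeze_h * bandwidth_multiplier
    pos_surf = kde_surface(pos, h, grid)
    neg_surf = kde_surface(neg, h, grid)
    return sors_surface(pos_surf, neg_surf).values.ravel()


def run_scenario(
    spec: ScenarioSpec,
    data: StudyData,
    eps: np.ndarray,
    boots: BootstrapSet,
    recompute_bandwidth: bool = True,
) -> ScoreMatrix:
    """Score matrix for one scenario: rebuild surfaces per bootstrap replicate.

    For each replicate the two layers are replaced by their resamples, the
    pooled bandwidth is recomputed on the resample (unless
    ``recompute_bandwidth`` is False, which freezes the full-data bandwidth)
    and scaled by the scenario multiplier, both KDE surfaces and their
    difference are rebuilt on the scenario grid, and the score is read off at
    every evaluation point with the scenario's interpolator.
    """
    eps = np.atleast_2d(np.asarray(eps, dtype=float))
    weighted = assign_weights(data.points, _scheme_for(spec.weighting))
    pos = weighted.select_layer("obesogenic")
    neg = weighted.select_layer("protective")
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both layers must be non-empty")
    if boots.pos_idx.shape[1] != len(pos) or boots.neg_idx.shape[1] != len(neg):
        raise ValueError("bootstrap index sizes do not match the layers")
    grid = _resolve_grid(data, spec)

    base_h = pooled_os_bandwidth(pos, neg)
    variogram: VariogramModel | None = None
    if spec.interp_method == "kriging":
        # variogram fitted once on the base (non-bootstrap) surface and reused
        base_vals = _build_score_values(pos, neg, grid, spec.bandwidth_multiplier)
        from .kde_score import ScoreSurface

        base_surface = ScoreSurface(
            grid=grid,
            values=base_vals.reshape(grid.nx, grid.ny),
            layer="sors",
            h=base_h.h * spec.bandwidth_multiplier,
        )
        variogram = fit_variogram(base_surface)
    w_matrix = interp_node_weights(
        grid, eps, spec.interp_method, variogram=variogram
    )

    values = np.empty((len(eps), boots.B))
    for b in range(boots.B):
        pos_b = pos.subset(boots.pos_idx[b])
        neg_b = neg.subset(boots.neg_idx[b])
        node_vals = _build_score_values(
            pos_b,
            neg_b,
            grid,
            spec.bandwidth_multiplier,
            freeze_h=None if recompute_bandwidth else base_h.h,
        )
        values[:, b] = w_matrix @ node_vals
    return ScoreMatrix(values=values, scenario_id=spec.level_id)


def anova_f(m: ScoreMatrix | np.ndarray) -> float:
    """One-way ANOVA F over evaluation-point groups of bootstrap replicates.

    F = [sum_i B (ybar_i - ybar)^2 / (N-1)] / [sum_ib (y_ib - ybar_i)^2 / (N(B-1))].
    Zero within-group variance returns +inf with a warning.
    """
    y = m.values if isinstance(m, ScoreMatrix) else np.asarray(m, dtype=float)
    n_groups, b = y.shape
    if n_groups < 2 or b < 2:
        raise ValueError("need at least 2 groups and 2 replicates")
    group_means = y.mean(axis=1)
    grand = y.mean()
    between = b * np.sum((group_means - grand) ** 2) / (n_groups - 1)
    within = np.sum((y - group_means[:, None]) ** 2) / (n_groups * (b - 1))
    if within == 0.0:
        warnings.warn("zero within-group variance; F is +inf", stacklevel=2)
        return float("inf")
    return float(between / within)


def run_all_scenarios(
    data: StudyData,
    eps: np.ndarray,
    boots: BootstrapSet,
    area: str = "synthetic",
    recompute_bandwidth: bool = True,
) -> FTable:
    """F statistics for all 19 scenarios; the shared base case is computed once."""
    scenarios = table2_scenarios()
    base_f: float | None = None
    rows: list[FRow] = []
    for spec in scenarios:
        try:
            if spec.is_base_case and base_f is not None:
                f = base_f
            else:
                matrix = run_scenario(
                    spec, data, eps, boots, recompute_bandwidth=recompute_bandwidth
                )
                f = anova_f(matrix)
                if spec.is_base_case:
                    base_f = f
            rows.append(FRow(area=area, scenario_id=spec.level_id, parameter=spec.parameter, f_value=f))
        except Exception:
            logger.exception("scenario %s failed; row omitted", spec.level_id)
    return FTable(rows=rows)


def relative_influence(ftable: FTable) -> dict[str, float]:
    """Range of F within each parameter family, normalised by the base-case F.

    influence(family) = (max F - min F) / F_base, an explicit, simple
    normalisation of the F spread; raw F values remain the primary output.
    """
    influences: dict[str, float] = {}
    base_ids = {"bandwidth": "BW3", "edge_correction": "EC1", "grid_points": "GP1",
                "interpolation": "INT1", "weighting": "WT1"}
    for family, rows in ftable.by_family().items():
        fs = [r.f_value for r in rows]
        base = ftable.f_of(base_ids[family])
        influences[family] = (max(fs) - min(fs)) / base if base != 0 else float("inf")
    return influences
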