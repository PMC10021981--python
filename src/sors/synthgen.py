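"""Synthetic OSM-like fixtures: clustered POI layers plus a study boundary.

POI layers are drawn from a Thomas cluster process — Poisson parents with
Gaussian-dispersed Poisson offspring — which matches the clustered character
of real food- and activity-environment data (shops huddle along streets and
town centres).  The generator writes Overpass-style GeoJSON so every reader,
transform and scoring stage downstream is exercised exactly as it would be
on a real export, and returns a ground-truth record (all parameters and
parent locations) so tests can check recovery.

Default scale emulates a small rural town: a ~0.1 degree window holding a
few hundred POIs per layer, with obesogenic tags drawn from the unhealthy
food palette and protective tags from supermarkets, gyms, parks and bus
stops of the shipped default mapping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geodata_io import POIRecord, default_category_mapping
from .kde_score import Window
from .preprocess import PlanarPoints

# geographic default window (lon/lat degrees), roughly 7 x 11 km at 48.5 N
DEFAULT_WINDOW = Window(x0=10.0, x1=10.1, y0=48.5, y1=48.6)

DEFAULT_OBESOGENIC_MIX = {
    "amenity=fast_food": 0.35,
    "shop=bakery": 0.30,
    "shop=confectionery": 0.15,
    "amenity=bar": 0.20,
}
DEFAULT_PROTECTIVE_MIX = {
    "shop=supermarket": 0.20,
    "leisure=fitness_centre": 0.15,
    "leisure=park": 0.25,
    "leisure=pitch": 0.20,
    "highway=bus_stop": 0.20,
}


@dataclass
class ThomasParams:
    """Thomas cluster process parameters: parents ~ Poisson(kappa * area)."""

    kappa: float = 2000.0  # parent intensity per unit window area (deg^-2)
    mu: float = 12.0  # mean offspring per parent
    sigma: float = 0.004  # offspring dispersion (degrees, ~400 m)

    def __post_init__(self) -> None:
        if min(self.kappa, self.mu, self.sigma) <= 0:
            raise ValueError("kappa, mu and sigma must be positive")


@dataclass
class SyntheticConfig:
    window: Window = DEFAULT_WINDOW
    obesogenic: ThomasParams = field(default_factory=ThomasParams)
    protective: ThomasParams = field(default_factory=lambda: ThomasParams(kappa=1600.0, mu=14.0, sigma=0.005))
    obesogenic_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OBESOGENIC_MIX))
    protective_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROTECTIVE_MIX))
    boundary_points: int = 48  # vertices of the star-shaped boundary ring
    boundary_wobble: float = 0.25  # radial irregularity of the boundary
    seed: int = 0

    def __post_init__(self) -> None:
        for mix in (self.obesogenic_mix, self.protective_mix):
            total = sum(mix.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError(f"mixture proportions sum to {total}, expected 1")
            if any(p <= 0 for p in mix.values()):
                raise ValueError("mixture proportions must be positive")


def simulate_thomas(
    kappa: float,
    mu: float,
    sigma: float,
    window: Window,
    seed: int | np.random.Generator = 0,
    layer: str = "obesogenic",
    subcategory: str = "synthetic",
) -> tuple[PlanarPoints, np.ndarray]:
    """Simulate a Thomas cluster pattern inside ``window``.

    Parents are uniform on the window padded by 4 sigma on every side (so
    clusters straddling the border are not thinned) with expected count
    kappa * padded area; each parent emits Poisson(mu) offspring displaced
    by an isotropic Gaussian of scale sigma, and offspring falling outside
    the window are discarded.  Returns the retained offspring and the parent
    locations (ground truth).
    """
    if min(kappa, mu, sigma) <= 0:
        raise ValueError("kappa, mu and sigma must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pad = 4.0 * sigma
    px0, px1 = window.x0 - pad, window.x1 + pad
    py0, py1 = window.y0 - pad, window.y1 + pad
    area = (px1 - px0) * (py1 - py0)
    expected = kappa * area * mu
    if expected < 2:
        raise ValueError(f"expected offspring count {expected:.2f} < 2; raise kappa or mu")
    n_parents = rng.poisson(kappa * area)
    parents = rng.uniform([px0, py0], [px1, py1], size=(n_parents, 2))
    n_off = rng.poisson(mu, size=n_parents)
    centers = np.repeat(parents, n_off, axis=0)
    offspring = centers + rng.normal(0.0, sigma, size=centers.shape)
    inside = window.contains(offspring[:, 0], offspring[:, 1])
    offspring = offspring[inside]
    n = len(offspring)
    points = PlanarPoints(
        x=offspring[:, 0],
        y=offspring[:, 1],
        layer=np.full(n, layer, dtype=object),
        subcategory=np.full(n, subcategory, dtype=object),
        weights=np.ones(n),
    )
    return points, parents


def _star_boundary(window: Window, n_points: int, wobble: float, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Irregular star-shaped ring strictly inside the window."""
    cx, cy = window.center
    rx = 0.38 * window.width
    ry = 0.38 * window.height
    theta = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    radial = 1.0 + wobble * np.sin(5.0 * theta + phase) * rng.uniform(0.6, 1.0)
    ring = [
        (cx + rx * rr * math.cos(t), cy + ry * rr * math.sin(t))
        for t, rr in zip(theta, radial)
    ]
    return ring + [ring[0]]


def synthesize_dataset(
    cfg: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path, dict]:
    """Write Overpass-style POI and boundary GeoJSON files plus ground truth.

    POIs get OSM tag properties drawn from the per-layer mixtures; the
    boundary is a star-shaped ring inside the window.  The returned record
    holds every parameter, the parent locations and the per-point tags, so
    the generated data can be reconstructed and checked exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    features = []
    truth: dict = {"seed": cfg.seed, "layers": {}}
    for layer, params, mix in (
        ("obesogenic", cfg.obesogenic, cfg.obesogenic_mix),
        ("protective", cfg.protective, cfg.protective_mix),
    ):
        points, parents = simulate_thomas(
            params.kappa, params.mu, params.sigma, cfg.window, seed=rng, layer=layer
        )
        tags = list(mix.keys())
        probs = np.array([mix[t] for t in tags])
        chosen = rng.choice(len(tags), size=len(points), p=probs)
        for i in range(len(points)):
            key, value = tags[chosen[i]].split("=")
            features.append(
                {
                    "type": "Feature",
                    "id": f"{layer}/{i}",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [points.x[i], points.y[i]],
                    },
                    "properties": {key: value},
                }
            )
        truth["layers"][layer] = {
            "kappa": params.kappa,
            "mu": params.mu,
            "sigma": params.sigma,
            "n_points": len(points),
            "parents": parents.tolist(),
            "tags": [tags[c] for c in chosen],
        }

    poi_path = out_dir / "pois.geojson"
    with open(poi_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    ring = _star_boundary(cfg.window, cfg.boundary_points, cfg.boundary_wobble, rng)
    boundary_path = out_dir / "boundary.geojson"
    with open(boundary_path, "w") as fh:
        json.dump(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"name": "synthetic study area"},
            },
            fh,
        )
    truth["boundary_ring"] = ring
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh)
    return poi_path, boundary_path, truth


# ---------------------------------------------------------------------------
# the six-POI worked example
# ---------------------------------------------------------------------------

_TABLE1_ROWS = [
    ("obesogenic", "Unhealthy_food", "Pastry", 0.2595, 0.3189),
    ("obesogenic", "Unhealthy_food", "Pastry", 0.2488, 0.3161),
    ("obesogenic", "Unhealthy_food", "Sweets", 0.2303, 0.2657),
    ("protective", "Physical_activity", "Canoe", 0.2789, 0.2966),
    ("protective", "Physical_activity", "Climbing", 0.2404, 0.2867),
    ("protective", "Physical_activity", "Climbing", 0.3009, 0.2084),
]

_TABLE1_TAGS = {
    "Pastry": ("shop", "pastry"),
    "Sweets": ("shop", "confectionery"),
    "Canoe": ("sport", "canoe"),
    "Climbing": ("sport", "climbing"),
}


def table1_fixture() -> list[POIRecord]:
    """The six-POI worked example, already in planar coordinates.

    Coordinates are relative to the synthetic southwest origin after the
    equidistant transform, so they are loaded as planar and never re-projected.
    """
    return [
        POIRecord(
            id=f"t1/{i}",
            lon=x,
            lat=y,
            layer=layer,
            category=cat,
            subcategory=sub,
        )
        for i, (layer, cat, sub, x, y) in enumerate(_TABLE1_ROWS)
    ]


def table1_planar_points() -> PlanarPoints:
    """The six-POI fixture as a planar point set (unit weights)."""
    recs = table1_fixture()
    return PlanarPoints(
        x=[r.lon for r in recs],
        y=[r.lat for r in recs],
        layer=[r.layer for r in recs],
        subcategory=[r.subcategory for r in recs],
        weights=np.ones(len(recs)),
    )


def table1_geojson(path: str | Path) -> Path:
    """Write the six-POI fixture as an OSM-tagged GeoJSON FeatureCollection."""
    features = []
    for i, (layer, cat, sub, x, y) in enumerate(_TABLE1_ROWS):
        key, value = _TABLE1_TAGS[sub]
        features.append(
            {
                "type": "Feature",
                "id": f"t1/{i}",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {key: value},
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def mapping_roundtrip_check() -> bool:
    """True if every default-mixture tag resolves in the default mapping."""
    mapping = default_category_mapping()
    for mix, layer in ((DEFAULT_OBESOGENIC_MIX, "obesogenic"), (DEFAULT_PROTECTIVE_MIX, "protective")):
        for tag in mix:
            triple = mapping.entries.get(tag)
            if triple is None or triple[0] != layer:
                return False
    return True
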