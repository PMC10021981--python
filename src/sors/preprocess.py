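"""Planar transform, bus-stop reduction and scenario weighting.

Geographic coordinates are mapped to an equidistant planar frame by the
equirectangular scaling x = (lon - lon0) * cos(ref_lat), y = lat - lat0,
with a synthetic origin (lon0, lat0) placed strictly southwest of all data so
every planar coordinate is positive.  One unit of x then spans the same
ground distance as one unit of y, which is what the kernel (isotropic in
planar units) and Ripley's K (Euclidean interpoint distances) require.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from shapely.affinity import translate, scale as shapely_scale
from sklearn.cluster import DBSCAN

from .geodata_io import BoundaryPolygon, POIRecord

logger = logging.getLogger(__name__)

# pad in degrees placed between the data's bounding box and the synthetic origin
ORIGIN_PAD_DEG = 0.05


@dataclass
class PlanarPoints:
    """Point set in the equidistant planar frame with layer labels and weights."""

    x: np.ndarray
    y: np.ndarray
    layer: np.ndarray  # str array, 'obesogenic' | 'protective'
    subcategory: np.ndarray  # str array
    weights: np.ndarray
    origin: tuple[float, float] | None = None  # (lon0, lat0); None for born-planar data
    ref_lat: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.layer = np.asarray(self.layer, dtype=object)
        self.subcategory = np.asarray(self.subcategory, dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.x)
        if not (len(self.y) == len(self.layer) == len(self.subcategory) == len(self.weights) == n):
            raise ValueError("field lengths differ")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def select_layer(self, layer: str) -> "PlanarPoints":
        mask = self.layer == layer
        return self.subset(np.flatnonzero(mask))

    def subset(self, idx: np.ndarray) -> "PlanarPoints":
        return PlanarPoints(
            x=self.x[idx],
            y=self.y[idx],
            layer=self.layer[idx],
            subcategory=self.subcategory[idx],
            weights=self.weights[idx],
            origin=self.origin,
            ref_lat=self.ref_lat,
        )


@dataclass
class WeightingScheme:
    """Per-subcategory weight multipliers; 'equal' maps everything to 1."""

    name: str = "equal"
    multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ("equal", "double_supermarket_gym", "custom"):
            raise ValueError(f"unknown weighting scheme {self.name!r}")
        if self.name == "double_supermarket_gym" and not self.multipliers:
            self.multipliers = {"supermarket": 2.0, "gym": 2.0}
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be positive")

    def multiplier_for(self, subcategory: str) -> float:
        if self.name == "equal":
            return 1.0
        return self.multipliers.get(subcategory, 1.0)


def _planar_xy(
    lon: np.ndarray, lat: np.ndarray, origin: tuple[float, float], ref_lat: float
) -> tuple[np.ndarray, np.ndarray]:
    cosref = math.cos(math.radians(ref_lat))
    return (lon - origin[0]) * cosref, lat - origin[1]


def equidistant_transform(
    records: Sequence[POIRecord], boundary: BoundaryPolygon
) -> tuple[PlanarPoints, BoundaryPolygon]:
    """Project records and boundary into the equidistant planar frame.

    The reference latitude is the mean latitude of the joint bounding box of
    POIs and boundary; the synthetic origin sits ``ORIGIN_PAD_DEG`` degrees
    southwest of that box, so all planar coordinates come out positive.
    """
    if not records:
        raise ValueError("no POI records to transform")
    if boundary.crs_state != "geographic":
        raise ValueError("boundary already planar")
    lon = np.array([r.lon for r in records])
    lat = np.array([r.lat for r in records])
    bx0, by0, bx1, by1 = boundary.polygon.bounds
    lon_min = min(lon.min(), bx0)
    lat_min = min(lat.min(), by0)
    lat_max = max(lat.max(), by1)
    origin = (lon_min - ORIGIN_PAD_DEG, lat_min - ORIGIN_PAD_DEG)
    ref_lat = 0.5 * (lat_min + lat_max)

    x, y = _planar_xy(lon, lat, origin, ref_lat)
    points = PlanarPoints(
        x=x,
        y=y,
        layer=np.array([r.layer for r in records], dtype=object),
        subcategory=np.array([r.subcategory for r in records], dtype=object),
        weights=np.array([r.weight for r in records]),
        origin=origin,
        ref_lat=ref_lat,
    )
    cosref = math.cos(math.radians(ref_lat))
    planar_poly = shapely_scale(
        translate(boundary.polygon, xoff=-origin[0], yoff=-origin[1]),
        xfact=cosref,
        yfact=1.0,
        origin=(0, 0),
    )
    return points, BoundaryPolygon(polygon=planar_poly, crs_state="planar")


def inverse_equidistant_transform(points: PlanarPoints) -> tuple[np.ndarray, np.ndarray]:
    """Map planar coordinates back to (lon, lat) degrees."""
    if points.origin is None or points.ref_lat is None:
        raise ValueError("points carry no transform provenance")
    cosref = math.cos(math.radians(points.ref_lat))
    return points.x / cosref + points.origin[0], points.y + points.origin[1]


def reduce_bus_stops(
    points: PlanarPoints,
    subcategory: str = "Bus_stop",
    eps: float = 0.004,
    min_pts: int = 3,
) -> PlanarPoints:
    """Replace dense groups of one subcategory by their centroids via DBSCAN.

    Each DBSCAN cluster collapses to a single unit-weight point at the
    coordinate mean; noise points (sparse stops) are kept as-is, and every
    other subcategory passes through untouched.  The default ``eps`` of 0.004
    planar units corresponds to roughly 300 m near the study latitudes.
    """
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    mask = points.subcategory == subcategory
    if not mask.any():
        logger.warning("subcategory %r not present; returning input unchanged", subcategory)
        return points
    keep = points.subset(np.flatnonzero(~mask))
    bus = points.subset(np.flatnonzero(mask))
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(bus.coords)

    xs, ys, layers, subs, wts = (
        list(keep.x),
        list(keep.y),
        list(keep.layer),
        list(keep.subcategory),
        list(keep.weights),
    )
    noise = labels == -1
    for i in np.flatnonzero(noise):
        xs.append(bus.x[i])
        ys.append(bus.y[i])
        layers.append(bus.layer[i])
        subs.append(subcategory)
        wts.append(bus.weights[i])
    for lab in np.unique(labels[~noise]):
        members = labels == lab
        xs.append(bus.x[members].mean())
        ys.append(bus.y[members].mean())
        layers.append(bus.layer[np.flatnonzero(members)[0]])
        subs.append(subcategory)
        wts.append(1.0)  # centroid replaces the cluster, it does not re-weight it
    return PlanarPoints(
        x=np.array(xs),
        y=np.array(ys),
        layer=np.array(layers, dtype=object),
        subcategory=np.array(subs, dtype=object),
        weights=np.array(wts),
        origin=points.origin,
        ref_lat=points.ref_lat,
    )


def assign_weights(points: PlanarPoints, scheme: WeightingScheme) -> PlanarPoints:
    """Return a copy with weights set from the scheme's subcategory multipliers."""
    weights = np.array([scheme.multiplier_for(sub) for sub in points.subcategory])
    return replace(points, weights=weights)
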