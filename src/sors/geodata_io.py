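"""Reading and writing POI collections, boundaries, mappings and result tables.

POIs arrive as RFC 7946 GeoJSON FeatureCollections of Point features whose
``properties`` carry OSM-style tags (as produced by Overpass-style exports).
A :class:`CategoryMapping` translates tag pairs into the two risk layers and
their category/subcategory labels; features matching no entry are dropped
with a logged count, since raw exports carry plenty of extraneous tags.

Tabular outputs (K tables, ANOVA F tables, gridded surfaces) are plain CSV
with full float precision so that ``read(write(x)) == x``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from shapely.geometry import Polygon, shape

logger = logging.getLogger(__name__)

LAYERS = ("obesogenic", "protective")


@dataclass
class POIRecord:
    """One categorized point of interest.

    ``lon``/``lat`` are geographic degrees unless the record was produced in
    an already-planar frame (see :func:`sors.synthgen.table1_fixture`).
    """

    id: str
    lon: float
    lat: float
    layer: str
    category: str
    subcategory: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates ({self.lon}, {self.lat}) outside valid range")
        if not self.weight > 0:
            raise ValueError("weight must be positive")


@dataclass
class CategoryMapping:
    """Function from OSM tag pairs ``key=value`` to (layer, category, subcategory)."""

    entries: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def lookup(self, properties: dict) -> tuple[str, str, str] | None:
        """Return (layer, category, subcategory) for the first matching tag, else None."""
        for key, value in properties.items():
            hit = self.entries.get(f"{key}={value}")
            if hit is not None:
                return hit
        return None

    @property
    def subcategories(self) -> set[str]:
        return {sub for (_, _, sub) in self.entries.values()}


@dataclass
class BoundaryPolygon:
    """Study-area boundary ring; ``crs_state`` is 'geographic' or 'planar'."""

    polygon: Polygon
    crs_state: str = "geographic"

    def __post_init__(self) -> None:
        if self.crs_state not in ("geographic", "planar"):
            raise ValueError(f"invalid crs_state {self.crs_state!r}")
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError("boundary polygon must have positive area")
        if not self.polygon.is_valid:
            raise ValueError("boundary polygon is self-intersecting or otherwise invalid")


class ConfigurationError(ValueError):
    """Raised for contradictory or malformed category-mapping files."""


def _build_mapping(doc: dict, source: str) -> CategoryMapping:
    entries: dict[str, tuple[str, str, str]] = {}
    for entry in doc.get("entries", []):
        tag = entry["tag"]
        layer = entry["layer"]
        if layer not in LAYERS:
            raise ConfigurationError(f"{source}: unknown layer {layer!r} for tag {tag!r}")
        triple = (layer, entry["category"], entry["subcategory"])
        if tag in entries and entries[tag][0] != triple[0]:
            raise ConfigurationError(
                f"{source}: tag {tag!r} mapped to both {entries[tag][0]!r} and {layer!r}"
            )
        entries[tag] = triple
    return CategoryMapping(entries=entries)


def load_category_mapping(path: str | Path) -> CategoryMapping:
    """Load a tag mapping from a YAML file; conflicting duplicate tags are an error."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ConfigurationError(f"{path}: expected a mapping document with an 'entries' list")
    return _build_mapping(doc, str(path))


def default_category_mapping() -> CategoryMapping:
    """The shipped default tag mapping (user files override it entirely)."""
    text = resources.files("sors.data").joinpath("default_mapping.yaml").read_text()
    return _build_mapping(yaml.safe_load(text), "default_mapping.yaml")


def read_poi_collection(path: str | Path, mapping: CategoryMapping) -> list[POIRecord]:
    """Read a GeoJSON FeatureCollection of points into categorized records.

    Features whose tags match no mapping entry, and non-point geometries, are
    skipped; the counts are logged, not raised.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise IOError(f"{path}: not a GeoJSON FeatureCollection")
    records: list[POIRecord] = []
    n_unmatched = 0
    n_nonpoint = 0
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            n_nonpoint += 1
            continue
        props = feat.get("properties") or {}
        hit = mapping.lookup(props)
        if hit is None:
            n_unmatched += 1
            continue
        layer, category, subcategory = hit
        lon, lat = geom["coordinates"][:2]
        records.append(
            POIRecord(
                id=str(feat.get("id", props.get("id", i))),
                lon=float(lon),
                lat=float(lat),
                layer=layer,
                category=category,
                subcategory=subcategory,
            )
        )
    if n_nonpoint:
        logger.warning("%s: skipped %d non-point geometries", path, n_nonpoint)
    if n_unmatched:
        logger.info("%s: %d features matched no mapping entry and were dropped", path, n_unmatched)
    return records


def read_boundary(path: str | Path, crs_state: str = "geographic") -> BoundaryPolygon:
    """Read the study boundary: the largest polygon in a GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    polys: list[Polygon] = []

    def collect(geom_doc: dict) -> None:
        gtype = geom_doc.get("type")
        if gtype in ("Polygon", "MultiPolygon"):
            geom = shape(geom_doc)
            if gtype == "Polygon":
                polys.append(geom)
            else:
                polys.extend(geom.geoms)

    if doc.get("type") == "FeatureCollection":
        for feat in doc.get("features", []):
            if feat.get("geometry"):
                collect(feat["geometry"])
    elif doc.get("type") == "Feature":
        if doc.get("geometry"):
            collect(doc["geometry"])
    else:
        collect(doc)
    if not polys:
        raise IOError(f"{path}: no polygon found")
    largest = max(polys, key=lambda p: p.area)
    return BoundaryPolygon(polygon=largest, crs_state=crs_state)


# ---------------------------------------------------------------------------
# tabular writers / readers (full-precision CSV; read(write(x)) == x)
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def write_f_table(ftable, path: str | Path) -> None:
    """Write an ANOVA F table as CSV rows (area, scenario, parameter, F)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["area", "scenario", "parameter", "F"])
        for row in ftable.rows:
            w.writerow([row.area, row.scenario_id, row.parameter, _fmt(row.f_value)])


def read_f_table(path: str | Path):
    from .evaluate import FTable, FRow

    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                FRow(
                    area=rec["area"],
                    scenario_id=rec["scenario"],
                    parameter=rec["parameter"],
                    f_value=float(rec["F"]),
                )
            )
    return FTable(rows=rows)


def write_surface(surface, path: str | Path) -> None:
    """Write a gridded surface as x,y,value CSV (row-major over the grid)."""
    grid = surface.grid
    xs, ys = grid.node_axes()
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# layer={surface.layer} nx={grid.nx} ny={grid.ny} h={_fmt(surface.h)}"
            f" window={_fmt(grid.window.x0)},{_fmt(grid.window.x1)},"
            f"{_fmt(grid.window.y0)},{_fmt(grid.window.y1)}\n"
        )
        w = csv.writer(fh)
        w.writerow(["x", "y", "value"])
        for j in range(grid.ny):
            for i in range(grid.nx):
                w.writerow([_fmt(xs[i]), _fmt(ys[j]), _fmt(surface.values[i, j])])


def read_surface(path: str | Path):
    from .kde_score import DensitySurface, Grid, ScoreSurface, Window

    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(item.split("=", 1) for item in header.split())
        reader = csv.DictReader(fh)
        vals = [float(rec["value"]) for rec in reader]
    nx, ny = int(meta["nx"]), int(meta["ny"])
    x0, x1, y0, y1 = (float(v) for v in meta["window"].split(","))
    window = Window(x0=x0, x1=x1, y0=y0, y1=y1)
    grid = Grid(window=window, nx=nx, ny=ny)
    values = np.array(vals).reshape(ny, nx).T
    cls = ScoreSurface if meta["layer"] == "sors" else DensitySurface
    return cls(grid=grid, values=values, layer=meta["layer"], h=float(meta["h"]))


def write_k_table(kest, path: str | Path) -> None:
    """Write a K-function estimate as r,K,pois,lo,hi CSV."""
    have_bands = kest.lo is not None
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["r", "k_hat", "k_pois", "lo", "hi"])
        for i, r in enumerate(kest.r):
            row = [_fmt(r), _fmt(kest.k_hat[i]), _fmt(kest.k_pois[i])]
            row += [_fmt(kest.lo[i]), _fmt(kest.hi[i])] if have_bands else ["", ""]
            w.writerow(row)


def read_k_table(path: str | Path) -> dict[str, np.ndarray | None]:
    cols: dict[str, list[float]] = {"r": [], "k_hat": [], "k_pois": [], "lo": [], "hi": []}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            for name in cols:
                if rec[name] != "":
                    cols[name].append(float(rec[name]))
    out: dict[str, np.ndarray | None] = {}
    for name, vals in cols.items():
        out[name] = np.asarray(vals) if vals else None
    return out


def write_poi_collection(records: Iterable[POIRecord], path: str | Path) -> None:
    """Write records back to GeoJSON, tags reconstructed as category properties."""
    features = []
    for rec in records:
        features.append(
            {
                "type": "Feature",
                "id": rec.id,
                "geometry": {"type": "Point", "coordinates": [rec.lon, rec.lat]},
                "properties": {
                    "layer": rec.layer,
                    "category": rec.category,
                    "subcategory": rec.subcategory,
                    "weight": rec.weight,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
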