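"""Seed-area polygons and daily release cohorts.

Virtual larvae enter the simulation inside natal-habitat polygons (in the
field setting, reef habitat mapped from the shoreline to the 150 m depth
contour).  Releases happen daily over the first days of a run: a fixed number
of particles, uniformly distributed across all seed polygons, per release day.
Polygon construction from bathymetry is out of scope — polygons are inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

_REJECTION_CAP = 1_000_000  # attempts per polygon; guards degenerate slivers


class SeedingError(ValueError):
    """Invalid seed polygons or release parameters."""


@dataclass
class SeedPolygonSet:
    """A collection of seed-area polygons with planar areas.

    Areas are planar (degree-space) and used only for proportional allocation
    of particles among polygons; seed areas span a few degrees of latitude at
    most, so the distortion is a documented, small limitation.  Polygons may
    carry interior rings (e.g. annular reef belts around an island).
    """

    polygons: list[Polygon]
    areas: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.polygons:
            raise SeedingError("empty polygon set")
        for i, p in enumerate(self.polygons):
            if not isinstance(p, Polygon):
                raise SeedingError(f"entry {i} is not a polygon")
            # zero-area slivers are tolerated here and skipped at sampling time
            if not p.is_valid and p.area > 0:
                raise SeedingError(f"polygon {i} is invalid (self-intersecting?)")
            if len(p.exterior.coords) < 4:  # ring closure repeats first vertex
                raise SeedingError(f"polygon {i} has fewer than 3 distinct vertices")
        self.areas = np.array([p.area for p in self.polygons], dtype=float)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass(frozen=True)
class ReleaseSchedule:
    """When cohorts enter the simulation: ``seed_days`` daily releases of
    ``particles_per_day`` particles each (full-scale run: 10 x 202,240)."""

    seed_days: int
    particles_per_day: int

    @property
    def total(self) -> int:
        return self.seed_days * self.particles_per_day

    @property
    def release_day_indices(self) -> range:
        return range(self.seed_days)


def build_release_schedule(seed_days: int, particles_per_day: int) -> ReleaseSchedule:
    """Validated release schedule; total = seed_days x particles_per_day."""
    for name, val, lo in (("seed_days", seed_days, 1), ("particles_per_day", particles_per_day, 0)):
        if not isinstance(val, (int, np.integer)) or isinstance(val, bool):
            raise SeedingError(f"{name} must be an integer, got {val!r}")
        if val < lo:
            raise SeedingError(f"{name} must be >= {lo}, got {val}")
    return ReleaseSchedule(int(seed_days), int(particles_per_day))


def sample_polygon_points(
    polyset: SeedPolygonSet, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` points uniformly over the union of the seed polygons.

    Allocation among polygons is multinomial with probabilities proportional
    to planar area, then uniform rejection sampling within each polygon's
    bounding box.  Returns an (n, 2) array of (lon, lat).
    """
    if n < 0:
        raise SeedingError(f"n must be >= 0, got {n}")
    if n == 0:
        return np.empty((0, 2), dtype=float)

    areas = polyset.areas.copy()
    zero = areas <= 0.0
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} zero-area seed polygon(s)")
        areas[zero] = 0.0
    if areas.sum() <= 0.0:
        raise SeedingError("all seed polygons have zero area")

    alloc = rng.multinomial(n, areas / areas.sum())
    out = np.empty((n, 2), dtype=float)
    pos = 0
    for poly, k in zip(polyset.polygons, alloc):
        if k == 0:
            continue
        minx, miny, maxx, maxy = poly.bounds
        got = 0
        attempts = 0
        while got < k:
            if attempts > _REJECTION_CAP:
                raise SeedingError(
                    f"rejection sampling exceeded {_REJECTION_CAP} attempts "
                    f"for polygon with bounds {poly.bounds}"
                )
            m = max(k - got, 64)
            xs = rng.uniform(minx, maxx, m)
            ys = rng.uniform(miny, maxy, m)
            keep = shapely.contains_xy(poly, xs, ys)
            take = min(int(keep.sum()), k - got)
            idx = np.flatnonzero(keep)[:take]
            out[pos + got : pos + got + take, 0] = xs[idx]
            out[pos + got : pos + got + take, 1] = ys[idx]
            got += take
            attempts += m
        pos += k
    return out


def load_seed_polygons(path) -> SeedPolygonSet:
    """Read seed polygons from a GeoJSON file.

    Accepts Polygon / MultiPolygon geometries, bare, in a GeometryCollection
    or as a FeatureCollection; multi-polygons are flattened.
    """
    with open(path) as fh:
        gj = json.load(fh)

    geoms = []
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "GeometryCollection":
        geoms = [shape(g) for g in gj["geometries"]]
    else:
        geoms = [shape(gj)]

    polys: list[Polygon] = []
    for g in geoms:
        if isinstance(g, Polygon):
            polys.append(g)
        elif isinstance(g, MultiPolygon):
            polys.extend(g.geoms)
        else:
            raise SeedingError(f"unsupported geometry type {g.geom_type}")
    return SeedPolygonSet(polys)


def write_seed_polygons(polyset: SeedPolygonSet, path) -> None:
    """Write a polygon set as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"id": i}, "geometry": mapping(p)}
        for i, p in enumerate(polyset.polygons)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
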