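"""Geometry stages: polygon smoothing, concave hulls, accessible-area (M)
assembly from ecoregions, land clipping, and the sampling-bias surface.

All polygons are in WGS84 lon/lat. Area *fractions* (used by the 20%
ecoregion-coverage rule) are computed in a cylindrical equal-area projection
because raw lon/lat areas are latitude-distorted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform, unary_union

from .geodesy import meters_per_degree
from .grid import GridSpec

_AUTHALIC_R = 6371007.1809  # m; sphere with the WGS84 ellipsoid's surface area


def _cea_forward(x, y):
    """Cylindrical equal-area projection (meters)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return np.radians(x) * _AUTHALIC_R, np.sin(np.radians(y)) * _AUTHALIC_R


def equal_area_m2(geom: BaseGeometry) -> float:
    """Area of a lon/lat geometry in m^2 (cylindrical equal-area)."""
    if geom.is_empty:
        return 0.0
    return float(shp_transform(_cea_forward, geom).area)


def equal_area_km2(geom: BaseGeometry) -> float:
    return equal_area_m2(geom) / 1e6


# ---------------------------------------------------------------------------
# Chaikin corner-cutting smoothing
# ---------------------------------------------------------------------------

def _chaikin_ring(coords: np.ndarray, cut_ratio: float) -> np.ndarray:
    # closed ring without the duplicated last vertex
    nxt = np.roll(coords, -1, axis=0)
    q = coords + cut_ratio * (nxt - coords)
    r = coords + (1.0 - cut_ratio) * (nxt - coords)
    return np.column_stack([q, r]).reshape(-1, 2)


def chaikin_smooth(polygon: BaseGeometry, iterations: int = 3,
                   cut_ratio: float = 0.25) -> BaseGeometry:
    """Smooth polygon rings by Chaikin corner cutting.

    Each iteration replaces every edge by its ``cut_ratio`` and
    ``1 - cut_ratio`` points, doubling the ring's vertex count; rings stay
    closed. ``iterations=0`` returns the polygon unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not (0.0 < cut_ratio < 0.5):
        raise ValueError("cut_ratio must be in (0, 0.5)")
    if polygon.geom_type == "MultiPolygon":
        return unary_union([chaikin_smooth(p, iterations, cut_ratio) for p in polygon.geoms])
    if polygon.geom_type != "Polygon":
        raise ValueError(f"expected Polygon/MultiPolygon, got {polygon.geom_type}")

    def smooth_ring(ring_coords) -> np.ndarray:
        coords = np.asarray(ring_coords, float)[:-1]  # drop closing vertex
        if len(np.unique(coords, axis=0)) < 3:
            raise ValueError("degenerate ring: fewer than 3 distinct vertices")
        for _ in range(iterations):
            coords = _chaikin_ring(coords, cut_ratio)
        return coords

    shell = smooth_ring(polygon.exterior.coords)
    holes = [smooth_ring(h.coords) for h in polygon.interiors]
    return Polygon(shell, holes)


# ---------------------------------------------------------------------------
# Concave hull and M-area assembly
# ---------------------------------------------------------------------------

def concave_hull(points: Sequence[tuple[float, float]], concavity: float = 2.0) -> Polygon:
    """Concave (alpha-like) hull containing all input lon/lat points.

    ``concavity`` follows the concave-hull convention where larger values give
    simpler shapes and ``concavity -> inf`` recovers the convex hull; it is
    mapped onto shapely's ``ratio`` parameter as ``1 - 1/concavity``.
    """
    if concavity < 1.0:
        raise ValueError("concavity must be >= 1")
    pts = MultiPoint([Point(p) for p in points])
    if len(pts.geoms) < 3:
        raise ValueError("need at least 3 points")
    if pts.convex_hull.area == 0.0:
        raise ValueError("points are collinear")
    ratio = max(0.0, min(1.0, 1.0 - 1.0 / concavity))
    hull = shapely.concave_hull(pts, ratio=ratio, allow_holes=False)
    if hull.geom_type != "Polygon" or not hull.covers(pts):
        # fall back toward convexity until every point is covered
        hull = pts.convex_hull
    return hull


def buffered_points(points: Sequence[tuple[float, float]], radius_km: float = 25.0) -> BaseGeometry:
    """Union of geodesic point buffers; fallback hull for <3 or collinear points."""
    discs = []
    for lon, lat in points:
        mx, my = meters_per_degree(lat)
        dx, dy = radius_km * 1000.0 / mx, radius_km * 1000.0 / my
        circle = Point(lon, lat).buffer(1.0, quad_segs=32)
        discs.append(shapely.affinity.scale(circle, xfact=dx, yfact=dy, origin=(lon, lat)))
    return unary_union(discs)


@dataclass(frozen=True)
class Ecoregion:
    region_id: str
    polygon: BaseGeometry
    area_km2: float


class EcoregionSet:
    """Named building-block polygons for accessible-area construction."""

    def __init__(self, regions: Iterable[Ecoregion]):
        self.regions = list(regions)
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ecoregion ids")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @classmethod
    def from_polygons(cls, polygons: dict[str, BaseGeometry]) -> "EcoregionSet":
        return cls(Ecoregion(rid, poly, equal_area_km2(poly)) for rid, poly in polygons.items())


def build_m_area(hull: BaseGeometry, ecoregions: EcoregionSet,
                 min_coverage: float = 0.20) -> BaseGeometry:
    """Union of ecoregions whose area is covered >= ``min_coverage`` by the hull.

    Coverage fractions are equal-area; returns an empty polygon when no
    region qualifies.
    """
    if len(ecoregions) == 0:
        raise ValueError("empty ecoregion set")
    if hull.is_empty or not hull.is_valid:
        raise ValueError("hull must be a valid, non-empty geometry")
    keep = []
    for region in ecoregions:
        denom = equal_area_m2(region.polygon)
        if denom <= 0:
            continue
        frac = equal_area_m2(hull.intersection(region.polygon)) / denom
        if frac >= min_coverage - 1e-12:
            keep.append(region.polygon)
    if not keep:
        return Polygon()
    return unary_union(keep)


def clip_to_boundary(polygon: BaseGeometry, boundary: BaseGeometry) -> BaseGeometry:
    """Intersection with a boundary (e.g. land); empty result is not an error."""
    if not polygon.is_valid:
        polygon = shapely.make_valid(polygon)
    if not boundary.is_valid:
        boundary = shapely.make_valid(boundary)
    return polygon.intersection(boundary)


# ---------------------------------------------------------------------------
# Sampling-bias surface
# ---------------------------------------------------------------------------

def _nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference bandwidth (Scott/Silverman 'nrd' rule) for one axis."""
    n = x.size
    sd = float(np.std(x, ddof=1))
    q1, q3 = np.percentile(x, [25, 75])
    iqr = (q3 - q1) / 1.34
    spread = min(sd, iqr) if iqr > 0 else sd
    return 1.06 * spread * n ** (-0.2)


def bias_raster(lons: Sequence[float], lats: Sequence[float], grid: GridSpec,
                scale: float = 1000.0, decimals: int = 3) -> np.ndarray:
    """Sampling-effort surface from pooled occurrence points.

    Two-dimensional Gaussian product-kernel density with a normal-reference
    bandwidth per axis, evaluated at cell centers, multiplied by ``scale``
    and rounded to ``decimals`` places. Used to weight background
    availability so that a presence/background model factors out collection
    effort rather than fitting it.
    """
    x = np.asarray(lons, float)
    y = np.asarray(lats, float)
    if x.size < 2 or np.unique(np.column_stack([x, y]), axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct points for a bias surface")
    hx, hy = _nrd_bandwidth(x), _nrd_bandwidth(y)
    if hx <= 0 or hy <= 0:
        raise ValueError("zero bandwidth: points are collinear along an axis")
    lon_c, lat_c = grid.cell_centers()
    xc = lon_c[0]          # (ncols,)
    yc = lat_c[:, 0]       # (nrows,)
    kx = np.exp(-0.5 * ((xc[:, None] - x[None, :]) / hx) ** 2) / (hx * math.sqrt(2 * math.pi))
    ky = np.exp(-0.5 * ((yc[:, None] - y[None, :]) / hy) ** 2) / (hy * math.sqrt(2 * math.pi))
    density = ky @ kx.T / x.size  # (nrows, ncols)
    out = np.round(density * scale, decimals)
    if out.max() <= 0:
        raise ValueError("bias surface is zero everywhere; grid does not cover the points")
    return out
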