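"""Geodesic distances on the WGS84 ellipsoid.

Point-to-point distances use Vincenty's inverse formula. Point-to-polygon
distances project the polygon into a local equirectangular chart centered on
the point (scaled by the ellipsoid's radii of curvature at that latitude) and
measure the planar shapely distance there; at the sub-100-km scales relevant
to the 50-km candidate radius the chart error is negligible (<0.1%).
"""
from __future__ import annotations

import math

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)
_E2 = WGS84_F * (2.0 - WGS84_F)  # first eccentricity squared


def geodesic_m(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Geodesic distance in meters between two WGS84 points (Vincenty inverse)."""
    if lon1 == lon2 and lat1 == lat2:
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - WGS84_F) * math.tan(phi1))
    U2 = math.atan((1 - WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(200):
        sinLam, cosLam = math.sin(lam), math.cos(lam)
        sinSigma = math.sqrt(
            (cosU2 * sinLam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cosLam) ** 2
        )
        if sinSigma == 0.0:
            return 0.0
        cosSigma = sinU1 * sinU2 + cosU1 * cosU2 * cosLam
        sigma = math.atan2(sinSigma, cosSigma)
        sinAlpha = cosU1 * cosU2 * sinLam / sinSigma
        cos2Alpha = 1.0 - sinAlpha**2
        if cos2Alpha == 0.0:  # equatorial line
            cos2SigmaM = 0.0
        else:
            cos2SigmaM = cosSigma - 2.0 * sinU1 * sinU2 / cos2Alpha
        C = WGS84_F / 16.0 * cos2Alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos2Alpha))
        lamPrev = lam
        lam = L + (1.0 - C) * WGS84_F * sinAlpha * (
            sigma
            + C * sinSigma * (cos2SigmaM + C * cosSigma * (-1.0 + 2.0 * cos2SigmaM**2))
        )
        if abs(lam - lamPrev) < 1e-12:
            break
    else:
        # nearly antipodal: fall back to spherical law of cosines on the mean radius
        R = (2 * WGS84_A + WGS84_B) / 3.0
        d = math.acos(
            max(-1.0, min(1.0, math.sin(phi1) * math.sin(phi2)
                          + math.cos(phi1) * math.cos(phi2) * math.cos(L)))
        )
        return R * d

    u2 = cos2Alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    deltaSigma = B * sinSigma * (
        cos2SigmaM
        + B / 4.0 * (
            cosSigma * (-1.0 + 2.0 * cos2SigmaM**2)
            - B / 6.0 * cos2SigmaM * (-3.0 + 4.0 * sinSigma**2) * (-3.0 + 4.0 * cos2SigmaM**2)
        )
    )
    return WGS84_B * A * (sigma - deltaSigma)


def meters_per_degree(lat: float) -> tuple[float, float]:
    """(meters per degree longitude, meters per degree latitude) at a latitude."""
    phi = math.radians(lat)
    sin2 = math.sin(phi) ** 2
    N = WGS84_A / math.sqrt(1.0 - _E2 * sin2)           # prime vertical radius
    M = WGS84_A * (1.0 - _E2) / (1.0 - _E2 * sin2) ** 1.5  # meridional radius
    deg = math.pi / 180.0
    return N * math.cos(phi) * deg, M * deg


def local_chart(lon0: float, lat0: float):
    """Forward transform (lon, lat) -> local meters centered at (lon0, lat0)."""
    mx, my = meters_per_degree(lat0)

    def fwd(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x - lon0) * mx, (y - lat0) * my

    return fwd


def point_geometry_distance_m(lon: float, lat: float, geom: BaseGeometry) -> float:
    """Geodesic distance in meters from a point to a polygon/geometry (0 if inside)."""
    from shapely.geometry import Point

    if geom.is_empty:
        return math.inf
    if geom.covers(Point(lon, lat)):
        return 0.0
    local = local_chart(lon, lat)
    return float(shp_transform(local, geom).distance(Point(0.0, 0.0)))
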