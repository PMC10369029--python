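"""Geodesic distance and bearing on the WGS84 ellipsoid.

Vectorised Vincenty inverse solution. Tracking analyses in this package
(step distances, daily displacements, migration distances, route
straightness) all route through :func:`inverse` so that every distance in
the pipeline is an ellipsoidal geodesic, not a spherical approximation.
"""

from __future__ import annotations

import numpy as np

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)
_E2 = WGS84_F * (2.0 - WGS84_F)  # first eccentricity squared


def inverse(lat1, lon1, lat2, lon2, tol: float = 1e-12, max_iter: int = 100):
    """Solve the inverse geodesic problem.

    Parameters are degrees (scalars or broadcastable arrays). Returns
    ``(distance_m, initial_bearing_deg)``; the bearing is the forward
    azimuth at the first point, in [0, 360). Coincident points give
    distance 0 and bearing 0.
    """
    arrs = np.broadcast_arrays(*(np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2)))
    la1, lo1, la2, lo2 = arrs
    scalar = la1.ndim == 0
    la1, lo1, la2, lo2 = (np.atleast_1d(a) for a in (la1, lo1, la2, lo2))

    phi1 = np.radians(la1)
    phi2 = np.radians(la2)
    L = np.radians(lo2 - lo1)
    U1 = np.arctan((1.0 - WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1.0 - WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos2_alpha = np.ones_like(lam)
    cos_2sm = np.zeros_like(lam)
    sinlam = np.zeros_like(lam)
    coslam = np.ones_like(lam)

    for _ in range(max_iter):
        sinlam, coslam = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(cosU2 * sinlam, cosU1 * sinU2 - sinU1 * cosU2 * coslam)
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * coslam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        safe_ss = np.where(sin_sigma == 0.0, 1.0, sin_sigma)
        sin_alpha = np.where(sin_sigma == 0.0, 0.0, cosU1 * cosU2 * sinlam / safe_ss)
        cos2_alpha = 1.0 - sin_alpha**2
        safe_ca = np.where(cos2_alpha == 0.0, 1.0, cos2_alpha)
        # equatorial line: cos2_alpha == 0
        cos_2sm = np.where(cos2_alpha == 0.0, 0.0, cos_sigma - 2.0 * sinU1 * sinU2 / safe_ca)
        C = WGS84_F / 16.0 * cos2_alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos2_alpha))
        lam_new = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1.0 + 2.0 * cos_2sm**2))
        )
        if np.all(np.abs(lam_new - lam) < tol):
            lam = lam_new
            break
        lam = lam_new
    sinlam, coslam = np.sin(lam), np.cos(lam)
    sin_sigma = np.hypot(cosU2 * sinlam, cosU1 * sinU2 - sinU1 * cosU2 * coslam)
    cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * coslam
    sigma = np.arctan2(sin_sigma, cos_sigma)

    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A_ = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B_ = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B_ * sin_sigma * (
        cos_2sm
        + B_ / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sm**2)
            - B_ / 6.0 * cos_2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos_2sm**2)
        )
    )
    dist = WGS84_B * A_ * (sigma - delta_sigma)
    dist = np.where(sin_sigma == 0.0, 0.0, dist)

    bearing = np.degrees(np.arctan2(cosU2 * sinlam, cosU1 * sinU2 - sinU1 * cosU2 * coslam))
    bearing = np.where(sin_sigma == 0.0, 0.0, np.mod(bearing, 360.0))

    if scalar:
        return float(dist[0]), float(bearing[0])
    return dist, bearing


def distance(lat1, lon1, lat2, lon2):
    """Geodesic distance in metres (WGS84)."""
    return inverse(lat1, lon1, lat2, lon2)[0]


def initial_bearing(lat1, lon1, lat2, lon2):
    """Forward azimuth at the first point, degrees clockwise from north."""
    return inverse(lat1, lon1, lat2, lon2)[1]


def cumulative_distance(lats, lons) -> float:
    """Total along-track geodesic distance of a polyline, metres."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size < 2:
        return 0.0
    d, _ = inverse(lats[:-1], lons[:-1], lats[1:], lons[1:])
    return float(np.sum(d))


def meters_per_degree(lat) -> tuple:
    """Local metres per degree of latitude and longitude at ``lat``.

    Uses the WGS84 meridional (M) and prime-vertical (N) radii of
    curvature; adequate for sub-kilometre step conversions.
    """
    phi = np.radians(np.asarray(lat, dtype=float))
    s2 = np.sin(phi) ** 2
    M = WGS84_A * (1.0 - _E2) / (1.0 - _E2 * s2) ** 1.5
    N = WGS84_A / np.sqrt(1.0 - _E2 * s2)
    m_lat = np.pi / 180.0 * M
    m_lon = np.pi / 180.0 * N * np.cos(phi)
    return m_lat, m_lon
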