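"""Great-circle geometry helpers (spherical earth)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between two points (decimal degrees).

    Accepts scalars or numpy arrays (broadcasting applies).
    """
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def destination(lat, lon, bearing_deg, distance_m):
    """Destination point given start, initial bearing and distance."""
    delta = distance_m / EARTH_RADIUS_M
    theta = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return np.degrees(phi2), np.degrees(lam2)


def cumulative_track_m(lats, lons):
    """Cumulative along-track distance (m) over an ordered fix sequence."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size == 0:
        return np.array([])
    seg = haversine_m(lats[:-1], lons[:-1], lats[1:], lons[1:])
    return np.concatenate([[0.0], np.cumsum(seg)])


def project_to_track(lat, lon, track_lats, track_lons, track_cum_m):
    """Project a point onto a track polyline.

    Returns (along_m, offtrack_m): the along-track distance of the closest
    point on the polyline and the great-circle offset to it.  Segments are
    treated as locally planar (equirectangular about the segment), which is
    accurate for the hundreds-of-metres scales involved here.
    """
    tl = np.asarray(track_lats, dtype=float)
    tn = np.asarray(track_lons, dtype=float)
    if tl.size == 1:
        return float(track_cum_m[0]), float(haversine_m(lat, lon, tl[0], tn[0]))
    best = (np.inf, 0.0)
    coslat = np.cos(np.radians(lat))
    deg_m = np.pi * EARTH_RADIUS_M / 180.0
    for i in range(tl.size - 1):
        ax = (tn[i] - lon) * coslat * deg_m
        ay = (tl[i] - lat) * deg_m
        bx = (tn[i + 1] - lon) * coslat * deg_m
        by = (tl[i + 1] - lat) * deg_m
        dx, dy = bx - ax, by - ay
        seg2 = dx * dx + dy * dy
        t = 0.0 if seg2 == 0 else np.clip(-(ax * dx + ay * dy) / seg2, 0.0, 1.0)
        px, py = ax + t * dx, ay + t * dy
        off = float(np.hypot(px, py))
        if off < best[0]:
            along = track_cum_m[i] + t * (track_cum_m[i + 1] - track_cum_m[i])
            best = (off, float(along))
    return best[1], best[0]
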