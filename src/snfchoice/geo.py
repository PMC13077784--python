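"""Great-circle distances between coordinate pairs.

Distances drive two pieces of the referral analysis: membership of a
skilled nursing facility (SNF) in a hospital's choice set (the 22 km
radius and 15-nearest rules) and identification of each patient's
closest SNF for the counterfactual margins.  Haversine on a sphere of
mean radius 6371.0088 km is used throughout; at the sub-25 km scales
that matter here the discrepancy against an ellipsoidal geodesic is
below 0.3% and cannot flip any documented threshold.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
"""IUGG mean Earth radius, km."""


def _validate(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def distance_km(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in kilometres.

    Accepts scalars or broadcastable arrays of decimal degrees and
    returns kilometres with the same broadcast shape.  Symmetric,
    non-negative, and zero only for identical points.

    Raises
    ------
    ValueError
        If any coordinate is non-finite or outside valid bounds.
    """
    lat1 = np.asarray(lat1, dtype=float)
    lon1 = np.asarray(lon1, dtype=float)
    lat2 = np.asarray(lat2, dtype=float)
    lon2 = np.asarray(lon2, dtype=float)
    _validate(lat1, lon1)
    _validate(lat2, lon2)

    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards roundoff for antipodal points
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def cross_distance_km(lat_a, lon_a, lat_b, lon_b):
    """Pairwise distance matrix (len(a) x len(b)) in kilometres."""
    lat_a = np.atleast_1d(np.asarray(lat_a, dtype=float))
    lon_a = np.atleast_1d(np.asarray(lon_a, dtype=float))
    lat_b = np.atleast_1d(np.asarray(lat_b, dtype=float))
    lon_b = np.atleast_1d(np.asarray(lon_b, dtype=float))
    return distance_km(lat_a[:, None], lon_a[:, None], lat_b[None, :], lon_b[None, :])
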