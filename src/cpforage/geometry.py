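"""Spherical geometry helpers: great-circle distance and a local planar frame.

All pipeline distances are great-circle on a sphere of radius 6371.0088 km
(the IUGG mean Earth radius). Gridding and track simulation happen in a
colony-centred azimuthal-equidistant plane, in kilometres, so that radial
distance from the colony is preserved exactly and a square grid is
well-defined; tracks are converted back to lon/lat for storage so synthetic
data look exactly like field data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def path_length_km(lon, lat) -> float:
    """Summed great-circle length of a polyline given as coordinate arrays."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size < 2:
        return 0.0
    return float(np.sum(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])))


@dataclass(frozen=True)
class LocalProjection:
    """Azimuthal-equidistant projection centred on a reference point.

    Distances and azimuths from the centre are exact (spherical model);
    x is km east, y is km north of the centre.
    """

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) km in the local plane."""
        lam0 = np.radians(self.lon0)
        phi0 = np.radians(self.lat0)
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - lam0
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), -> 1 as c -> 0
        sin_c = np.sin(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(sin_c > 1e-12, c / np.where(sin_c > 1e-12, sin_c, 1.0), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, x, y):
        """(x, y) km -> (lon, lat) degrees."""
        lam0 = np.radians(self.lon0)
        phi0 = np.radians(self.lat0)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS_KM
        sin_c, cos_c = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            safe_rho = np.where(rho > 1e-12, rho, 1.0)
            phi = np.arcsin(np.clip(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / safe_rho, -1.0, 1.0))
            lam = lam0 + np.arctan2(x * sin_c, safe_rho * cos_c * np.cos(phi0) - y * sin_c * np.sin(phi0))
        phi = np.where(rho > 1e-12, phi, phi0)
        lam = np.where(rho > 1e-12, lam, lam0)
        return np.degrees(lam), np.degrees(phi)
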