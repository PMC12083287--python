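"""Great-circle distances between city coordinates."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance matrix (km) on a spherical Earth.

    Parameters
    ----------
    lon, lat : array-like of shape (n,)
        Coordinates in decimal degrees.

    Returns
    -------
    (n, n) ndarray of distances in kilometres; zero on the diagonal.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    dlon = lon[None, :] - lon[:, None]
    dlat = lat[None, :] - lat[:, None]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2.0) ** 2
    )
    # clip guards round-off for antipodal / identical points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
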