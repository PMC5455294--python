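"""Great-circle distances between sampled populations.

Spherical earth with R = 6371 km — the published "approximate distance"
column matches the sphere within 1%, so no ellipsoid is used. The span of a
species sampled at two or three sites is the mean of all pairwise distances
(for two sites, simply their distance).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def population_span_km(records: pd.DataFrame) -> float:
    """Mean pairwise great-circle distance of 2 or 3 populations of one species."""
    if not 2 <= len(records) <= 3:
        raise ValueError(f"need 2 or 3 populations, got {len(records)}")
    coords = records[["latitude", "longitude"]].to_numpy(dtype=float)
    dists = [
        haversine_km(a[0], a[1], b[0], b[1])
        for a, b in itertools.combinations(coords, 2)
    ]
    return float(np.mean(dists))


def species_span_table(populations: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean pairwise span for a population metadata table."""
    rows = [
        {"species": sp, "n_populations": len(sub), "span_km": population_span_km(sub)}
        for sp, sub in populations.groupby("species", sort=True)
        if len(sub) >= 2
    ]
    return pd.DataFrame(rows)
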