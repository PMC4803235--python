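"""Small geographic helpers shared across the pipeline.

Distances come in two flavours, mirroring the two conventions of the
analysis: thresholds quoted in degrees (site clustering at 0.4 deg, the
0.2 deg home-range buffer) use plain Euclidean distance in degree space,
while route arc lengths and metre-denominated buffers use great-circle
distance on a spherical Earth.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: km per degree of arc used for the plot-packing arithmetic.
KM_PER_DEG = 111.32


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcasting applies).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def degree_distance(lon1, lat1, lon2, lat2):
    """Euclidean distance in degree space, sqrt(dlon^2 + dlat^2)."""
    lon1, lat1, lon2, lat2 = (np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2))
    return np.hypot(lon2 - lon1, lat2 - lat1)
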