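"""Route construction and route-constrained availability sampling.

The migration route is the polyline joining the wintering origin, the
stopover medians in temporal order and the final position.  For each
stopover, "available" points are drawn uniformly in along-route arc
length within a +/- transect (default 184 km, one travel day) of the
stopover's position on the route, in several independent replicates,
enforcing a minimum degree-space separation so availability buffers do
not overlap the use buffer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import KM_PER_DEG, degree_distance, haversine_km
from .stopover import Site


class DegenerateRouteError(ValueError):
    pass


class SamplingInfeasibleError(RuntimeError):
    pass


@dataclass
class Route:
    """Polyline of a bird's migration with cumulative great-circle arc length."""

    bird_id: str
    lons: np.ndarray
    lats: np.ndarray
    cum_km: np.ndarray  # same length as lons; cum_km[0] == 0

    @property
    def total_km(self) -> float:
        return float(self.cum_km[-1])

    def point_at_km(self, s: float) -> tuple[float, float]:
        """Linear lon/lat interpolation at arc length ``s`` (clipped to ends)."""
        s = float(np.clip(s, 0.0, self.total_km))
        i = int(np.searchsorted(self.cum_km, s, side="right")) - 1
        i = min(max(i, 0), len(self.cum_km) - 2)
        seg = self.cum_km[i + 1] - self.cum_km[i]
        t = 0.0 if seg <= 0 else (s - self.cum_km[i]) / seg
        return (
            float(self.lons[i] + t * (self.lons[i + 1] - self.lons[i])),
            float(self.lats[i] + t * (self.lats[i + 1] - self.lats[i])),
        )


@dataclass
class AvailabilityPoint:
    bird_id: str
    stopover_id: int
    replicate: int  # 1-based
    point_index: int  # 1-based within replicate
    lon: float
    lat: float
    offset_km: float  # signed along-route offset from the stopover


def build_route(
    origin: tuple[float, float],
    stopovers: list[Site],
    terminus: tuple[float, float],
    bird_id: str | None = None,
) -> Route:
    """Route = origin -> stopover medians (temporal order) -> terminus."""
    pts = [origin] + [(s.median_lon, s.median_lat) for s in stopovers] + [terminus]
    # collapse consecutive duplicates so zero-length segments never appear
    dedup = [pts[0]]
    for p in pts[1:]:
        if p != dedup[-1]:
            dedup.append(p)
    if len(dedup) < 2:
        raise DegenerateRouteError("route needs at least 2 distinct waypoints")
    lons = np.array([p[0] for p in dedup], dtype=float)
    lats = np.array([p[1] for p in dedup], dtype=float)
    seg = haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    bid = bird_id or (stopovers[0].bird_id if stopovers else "")
    return Route(bid, lons, lats, cum)


def route_position_km(route: Route, lon: float, lat: float) -> float:
    """Arc-length position of a point on (or nearest to) the route.

    Projects onto each segment in lon/lat space and returns the cumulative
    km of the closest projection; stopover medians are route vertices so
    this is exact for them.
    """
    best_d, best_s = np.inf, 0.0
    for i in range(len(route.cum_km) - 1):
        ax, ay = route.lons[i], route.lats[i]
        bx, by = route.lons[i + 1], route.lats[i + 1]
        vx, vy = bx - ax, by - ay
        denom = vx * vx + vy * vy
        t = 0.0 if denom == 0 else float(np.clip(((lon - ax) * vx + (lat - ay) * vy) / denom, 0.0, 1.0))
        px, py = ax + t * vx, ay + t * vy
        d = float(np.hypot(lon - px, lat - py))
        if d < best_d:
            best_d = d
            best_s = float(route.cum_km[i] + t * (route.cum_km[i + 1] - route.cum_km[i]))
    return best_s


def max_disjoint_plots(transect_km: float, radius_deg: float) -> int:
    """How many non-overlapping circular plots of the given radius fit in the transect.

    floor(transect / plot diameter), with the diameter converted at
    111.32 km per degree: a 184 km transect holds four 0.2 deg plots.
    """
    if transect_km <= 0 or radius_deg <= 0:
        raise ValueError("transect and radius must be positive")
    return int(np.floor(transect_km / (2.0 * radius_deg * KM_PER_DEG)))


def sample_availability(
    route: Route,
    stopover: Site,
    stopover_id: int,
    n_points: int = 2,
    n_replicates: int = 4,
    transect_km: float = 184.0,
    min_sep_deg: float = 0.4,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 10_000,
    forward_only: bool = False,
) -> list[AvailabilityPoint]:
    """Draw replicate random availability points along the route.

    Offsets are uniform in arc length on [s-transect, s+transect]
    (or [s, s+transect] if ``forward_only``) clipped to the route ends;
    accepted points must lie >= ``min_sep_deg`` (degree space) from the
    stopover median and from other points of the same replicate.
    """
    rng = np.random.default_rng(rng)
    s0 = route_position_km(route, stopover.median_lon, stopover.median_lat)
    lo = max(0.0, s0 if forward_only else s0 - transect_km)
    hi = min(route.total_km, s0 + transect_km)
    if hi <= lo:
        raise SamplingInfeasibleError(f"stopover {stopover_id}: empty feasible arc")

    out: list[AvailabilityPoint] = []
    for rep in range(1, n_replicates + 1):
        accepted: list[tuple[float, float, float]] = []
        attempts = 0
        while len(accepted) < n_points:
            if attempts >= max_attempts:
                raise SamplingInfeasibleError(
                    f"stopover {stopover_id}: could not place {n_points} points "
                    f"with min separation {min_sep_deg} deg after {max_attempts} attempts"
                )
            attempts += 1
            s = float(rng.uniform(lo, hi))
            lon, lat = route.point_at_km(s)
            if degree_distance(lon, lat, stopover.median_lon, stopover.median_lat) < min_sep_deg:
                continue
            if any(degree_distance(lon, lat, alon, alat) < min_sep_deg for alon, alat, _ in accepted):
                continue
            accepted.append((lon, lat, s))
        for j, (lon, lat, s) in enumerate(accepted, start=1):
            out.append(AvailabilityPoint(route.bird_id, stopover_id, rep, j, lon, lat, s - s0))
    return out
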