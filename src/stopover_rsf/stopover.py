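"""Stopover-site detection from quality-filtered fixes.

Subsequent fixes of one bird closer than a degree-space threshold
(default 0.4 deg, the conservative bound on within-site Argos scatter)
chain into a *site*; the bird's position at a site is the per-coordinate
median of its member fixes.  Sites are classified by occupancy:
single_position (one fix), stopover (duration >= a minimum, default
2 days) or short_stop otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from .geo import degree_distance, haversine_km
from .telemetry import ArgosFix

SINGLE_POSITION = "single_position"
SHORT_STOP = "short_stop"
STOPOVER = "stopover"

HOURS_PER_DAY = 24.0


class UnsortedFixesError(ValueError):
    """Input fixes must be time-sorted and from a single bird."""


@dataclass
class Site:
    bird_id: str
    fixes: list[ArgosFix]
    category: str | None = None

    median_lon: float = field(init=False)
    median_lat: float = field(init=False)

    def __post_init__(self):
        if not self.fixes:
            raise ValueError("a site needs at least one fix")
        if len({f.bird_id for f in self.fixes}) != 1:
            raise ValueError("a site's fixes must come from one bird")
        self.median_lon = median(f.lon for f in self.fixes)
        self.median_lat = median(f.lat for f in self.fixes)

    @property
    def first_time(self):
        return self.fixes[0].timestamp

    @property
    def last_time(self):
        return self.fixes[-1].timestamp

    @property
    def duration_days(self) -> float:
        return (self.last_time - self.first_time).total_seconds() / 3600.0 / HOURS_PER_DAY

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


@dataclass
class SiteSummary:
    """Per-bird counts of each site category."""

    counts: dict[str, dict[str, int]]

    def total(self, category: str) -> int:
        return sum(c.get(category, 0) for c in self.counts.values())


def cluster_sites(
    fixes: list[ArgosFix],
    dist_threshold: float = 0.4,
    great_circle: bool = False,
    great_circle_threshold_km: float | None = None,
) -> list[Site]:
    """Chain time-ordered fixes of one bird into sites.

    A fix joins the current site iff its distance to the *previous fix*
    is below the threshold; otherwise a new site starts.  Distance is
    Euclidean in degree space by default (the threshold is quoted in
    degrees); set ``great_circle=True`` with a km threshold for a
    geodesic variant.
    """
    if not fixes:
        return []
    if len({f.bird_id for f in fixes}) != 1:
        raise UnsortedFixesError("cluster_sites expects fixes from a single bird")
    for a, b in zip(fixes, fixes[1:]):
        if b.timestamp < a.timestamp:
            raise UnsortedFixesError("fixes must be sorted ascending in time")

    sites: list[Site] = []
    current = [fixes[0]]
    for prev, fix in zip(fixes, fixes[1:]):
        if great_circle:
            thr = great_circle_threshold_km if great_circle_threshold_km is not None else dist_threshold * 111.32
            near = haversine_km(prev.lon, prev.lat, fix.lon, fix.lat) < thr
        else:
            near = degree_distance(prev.lon, prev.lat, fix.lon, fix.lat) < dist_threshold
        if near:
            current.append(fix)
        else:
            sites.append(Site(fixes[0].bird_id, current))
            current = [fix]
    sites.append(Site(fixes[0].bird_id, current))
    return sites


def classify_sites(sites: list[Site], min_stopover_days: float = 2.0) -> tuple[list[Site], SiteSummary]:
    """Label sites and return (stopovers, per-bird summary).

    single_position: one member fix; stopover: duration >= threshold;
    short_stop: everything in between.  Counts partition the site list.
    """
    counts: dict[str, dict[str, int]] = {}
    stopovers: list[Site] = []
    for site in sites:
        if site.n_fixes == 1:
            site.category = SINGLE_POSITION
        elif site.duration_days >= min_stopover_days:
            site.category = STOPOVER
            stopovers.append(site)
        else:
            site.category = SHORT_STOP
        bird = counts.setdefault(site.bird_id, {SINGLE_POSITION: 0, SHORT_STOP: 0, STOPOVER: 0})
        bird[site.category] += 1
    return stopovers, SiteSummary(counts)


def stopover_duration(site: Site) -> float:
    """Duration in days (first to last member fix) of a classified stopover."""
    if site.category != STOPOVER:
        raise ValueError("site is not a stopover")
    return site.duration_days


def sites_to_rows(sites: list[Site]) -> list[dict]:
    """Flatten sites for CSV export."""
    rows = []
    for i, s in enumerate(sites):
        rows.append(
            {
                "bird_id": s.bird_id,
                "site_id": i,
                "median_lon": s.median_lon,
                "median_lat": s.median_lat,
                "first_time": s.first_time.strftime("%Y-%m-%dT%H:%M:%S"),
                "last_time": s.last_time.strftime("%Y-%m-%dT%H:%M:%S"),
                "n_fixes": s.n_fixes,
                "duration_days": s.duration_days,
                "category": s.category,
            }
        )
    return rows
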