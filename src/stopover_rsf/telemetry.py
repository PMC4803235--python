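"""Argos fix data model, CSV I/O, quality filtering and duty-cycle arithmetic.

An Argos PTT (Platform Transmitter Terminal) alternates battery-charge
("off") and emission ("on") windows; each estimated position carries a
location class bounding its error: 3 (<250 m), 2 (250-500 m), 1 (500-1500 m),
0 (>1500 m), and A/B/Z with no usable accuracy estimate.  Only classes 0-3
are retained for analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

LOCATION_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")
GOOD_CLASSES = frozenset({"0", "1", "2", "3"})
#: Ranking used to break duplicate-timestamp ties: lower is better.
_CLASS_RANK = {c: i for i, c in enumerate(LOCATION_CLASSES)}

CSV_HEADER = ["bird_id", "timestamp", "lon", "lat", "loc_class"]


class FixFormatError(ValueError):
    """Raised when a fix table cannot be parsed; names the offending row."""


@dataclass(frozen=True)
class ArgosFix:
    bird_id: str
    timestamp: datetime  # UTC
    lon: float
    lat: float
    loc_class: str

    def __post_init__(self):
        if self.loc_class not in LOCATION_CLASSES:
            raise ValueError(f"unknown Argos location class {self.loc_class!r}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if self.timestamp.tzinfo is None:
            object.__setattr__(self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc))


@dataclass(frozen=True)
class DutyCycle:
    """Charge/emit schedule in hours, e.g. DutyCycle(48, 10) for a 48:10 tag."""

    off_hours: float
    on_hours: float

    def __post_init__(self):
        if self.off_hours <= 0 or self.on_hours <= 0:
            raise ValueError("duty-cycle phases must both be positive")

    @property
    def period_hours(self) -> float:
        return self.off_hours + self.on_hours


def min_gap_after_missed_window(dc: DutyCycle) -> float:
    """Minimal hours between possible fixes when one emission window yields none.

    The last chance in window k and the first chance in window k+1 are
    separated by at least off + on + off hours: a 48:10 tag that misses a
    whole window goes silent for >= 106 h (~4.4 days).
    """
    return dc.off_hours + dc.on_hours + dc.off_hours


def transmitter_load(device_mass_g: float, body_mass_g: float) -> float:
    """Tag load as a percentage of body mass (the '3% rule' check)."""
    if device_mass_g <= 0 or body_mass_g <= 0:
        raise ValueError("masses must be positive")
    return 100.0 * device_mass_g / body_mass_g


def filter_quality(fixes: Iterable[ArgosFix]) -> list[ArgosFix]:
    """Keep only good-quality fixes (location class 0-3), preserving order."""
    return [f for f in fixes if f.loc_class in GOOD_CLASSES]


def _parse_timestamp(raw: str, line_no: int) -> datetime:
    try:
        ts = datetime.fromisoformat(raw.strip())
    except ValueError as exc:
        raise FixFormatError(f"row {line_no}: unparseable timestamp {raw!r}") from exc
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _dedupe(fixes: list[ArgosFix]) -> list[ArgosFix]:
    # Same bird + same timestamp: keep the better location class, first on ties.
    best: dict[tuple[str, datetime], ArgosFix] = {}
    for f in fixes:
        key = (f.bird_id, f.timestamp)
        cur = best.get(key)
        if cur is None or _CLASS_RANK[f.loc_class] < _CLASS_RANK[cur.loc_class]:
            best[key] = f
    return list(best.values())


def read_fixes(path: str | Path) -> list[ArgosFix]:
    """Read a fix table CSV (header bird_id,timestamp,lon,lat,loc_class).

    Rows are de-duplicated and returned sorted by (bird, timestamp).
    """
    path = Path(path)
    fixes: list[ArgosFix] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FixFormatError(f"{path}: empty file, expected header {','.join(CSV_HEADER)}")
        if [h.strip() for h in header] != CSV_HEADER:
            raise FixFormatError(f"{path}: expected header {','.join(CSV_HEADER)}, got {','.join(header)}")
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise FixFormatError(f"row {line_no}: expected 5 columns, got {len(row)}")
            bird, ts_raw, lon_raw, lat_raw, lc = (c.strip() for c in row)
            ts = _parse_timestamp(ts_raw, line_no)
            try:
                lon, lat = float(lon_raw), float(lat_raw)
            except ValueError as exc:
                raise FixFormatError(f"row {line_no}: bad coordinate") from exc
            try:
                fixes.append(ArgosFix(bird, ts, lon, lat, lc))
            except ValueError as exc:
                raise FixFormatError(f"row {line_no}: {exc}") from exc
    fixes = _dedupe(fixes)
    fixes.sort(key=lambda f: (f.bird_id, f.timestamp))
    return fixes


def write_fixes(fixes: Sequence[ArgosFix], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for f in fixes:
            writer.writerow(
                [f.bird_id, f.timestamp.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S"), f"{f.lon:.6f}", f"{f.lat:.6f}", f.loc_class]
            )


def group_by_bird(fixes: Iterable[ArgosFix]) -> dict[str, list[ArgosFix]]:
    """Split a mixed fix list into per-bird time-sorted lists."""
    birds: dict[str, list[ArgosFix]] = {}
    for f in fixes:
        birds.setdefault(f.bird_id, []).append(f)
    for lst in birds.values():
        lst.sort(key=lambda f: f.timestamp)
    return birds
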