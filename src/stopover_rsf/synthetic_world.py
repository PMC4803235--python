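"""Synthetic landscapes and duty-cycled Argos-like tracks with known truth.

The generator emulates the study system end-to-end so every downstream
stage can be tested against ground truth:

* a categorical agro-forest land-cover raster on a geographic grid, with
  patch-scale mosaic structure and a cropland fraction that declines from
  west to east;
* spring migrations of satellite-tagged birds from a wintering box in
  northern Iberia to a breeding box in central Siberia (~6500 km at
  ~184 km/day), stopping over at points along the route;
* optional habitat-*biased landing*: the log-odds that a travel-day
  candidate becomes a stopover are ``beta_sel`` times the standardised
  cropland+mosaic fraction in a 0.2 deg buffer (``beta_sel = 0`` is the
  exact neutral null);
* optional habitat-*dependent duration*:
  ``duration = max(min_days, round(exp(a + beta_dur * score + noise)))``;
* Argos-like emission: fixes only inside the "on" windows of a duty cycle
  (default 48 h charge : 10 h emit), each satellite pass succeeding with a
  configurable probability, location classes drawn from a stated
  distribution with class-dependent positional noise (3 < 2 < 1 < 0) and
  unusable A/B/Z fixes injected at a configurable rate.

Because ``beta_sel`` and ``beta_dur`` act on a per-bird *standardised*
habitat score, they are log-odds (or log-duration) effects per standard
deviation of available habitat: ``beta = ln 3`` means an odds ratio of 3
per SD of cropland score.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np

from .geo import haversine_km
from .habitat import (
    CROPLAND_MOSAIC_LABELS,
    DEFAULT_NODATA,
    GLOBCOVER_LEGEND,
    LandCoverRaster,
    extract_composition,
)
from .telemetry import ArgosFix, DutyCycle


class InvalidConfigError(ValueError):
    pass


#: Baseline class mixture (weights, not yet gradient-adjusted), chosen to
#: resemble the reported stopover landscape: ~20% cropland, ~30% mosaic,
#: ~25% closed forest, the rest grass/shrub/sparse/urban/water.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "CRO1": 0.01,
    "CRO2": 0.20,
    "MOS1": 0.14,
    "MOS2": 0.10,
    "MOS3": 0.04,
    "MOS4": 0.04,
    "BFO2": 0.18,
    "NFO1": 0.07,
    "NFO2": 0.03,
    "MFO1": 0.08,
    "SHRU": 0.02,
    "GRAS": 0.05,
    "SVEG": 0.005,
    "FVE2": 0.01,
    "URBA": 0.01,
    "BARE": 0.005,
    "WATE": 0.02,
}

#: Location-class frequencies among usable fixes and the per-class
#: positional noise scale (km, isotropic Gaussian SD).  Noise respects the
#: accuracy bands: 3 < 250 m, 2 250-500 m, 1 500-1500 m, 0 > 1500 m.
DEFAULT_CLASS_PROBS = {"3": 0.15, "2": 0.25, "1": 0.35, "0": 0.25}
DEFAULT_NOISE_KM = {"3": 0.12, "2": 0.35, "1": 0.9, "0": 2.5, "A": 5.0, "B": 10.0, "Z": 30.0}


@dataclass
class WorldConfig:
    # raster
    lon_min: float = -10.0
    lon_max: float = 104.0
    lat_min: float = 40.0
    lat_max: float = 63.0
    cellsize: float = 0.0027  # deg, ~300 m at mid-latitudes
    patch_deg: float = 0.1  # mosaic patch scale
    region_deg: float = 0.75  # agricultural-intensity region scale
    region_sd: float = 0.8  # SD of the regional cropland-vs-forest log-odds factor
    class_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    cropland_gradient: float = 0.0015  # CRO2 weight increase per deg westwards
    # birds and routes
    n_birds: int = 9
    origin_box: tuple[float, float, float, float] = (-6.0, -1.0, 42.0, 44.0)  # lon0, lon1, lat0, lat1
    dest_box: tuple[float, float, float, float] = (90.0, 100.0, 56.0, 60.0)
    km_per_day: float = 184.0
    start_date: str = "2020-03-15"
    start_jitter_days: int = 8
    pre_days: int = 4  # stationary at the wintering site before departure
    post_days: int = 4  # stationary on arrival
    # stopovers
    stopover_mean: float = 2.8  # Poisson mean number of stopovers per bird
    stopover_min: int = 1
    duration_log_mean: float = math.log(5.0)  # a in exp(a + beta_dur*score + eps)
    duration_log_sd: float = 0.5
    min_stopover_days: int = 2
    beta_sel: float = 0.0  # log-odds of landing per SD of cropland score
    beta_dur: float = 0.0  # log-duration per SD of cropland score
    score_buffer_deg: float = 0.2
    # telemetry
    duty_off_hours: float = 48.0
    duty_on_hours: float = 10.0
    passes_per_window: int = 3
    pass_success: float = 0.8
    abz_rate: float = 0.15
    class_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    noise_km: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_KM))
    local_move_deg: float = 0.03  # within-site scatter beyond Argos noise
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.cellsize <= 0:
            raise InvalidConfigError("cell size must be > 0")
        if self.km_per_day <= 0:
            raise InvalidConfigError("daily flight distance must be > 0")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise InvalidConfigError("degenerate raster extent")
        for p in (self.pass_success, self.abz_rate):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError("probabilities must lie in [0, 1]")
        if not self.class_weights:
            raise InvalidConfigError("class legend/weights must be non-empty")
        unknown = set(self.class_weights) - set(GLOBCOVER_LEGEND.values())
        if unknown:
            raise InvalidConfigError(f"unknown land-cover labels {sorted(unknown)}")
        for box, name in ((self.origin_box, "origin"), (self.dest_box, "destination")):
            lon0, lon1, lat0, lat1 = box
            if not (self.lon_min <= lon0 <= lon1 <= self.lon_max and self.lat_min <= lat0 <= lat1 <= self.lat_max):
                raise InvalidConfigError(f"{name} box outside raster extent")

    @classmethod
    def demo(cls, seed: int = 0, **overrides) -> "WorldConfig":
        """A coarse-raster world (0.0125 deg cells, ~1.4 km) for demos and
        Monte-Carlo suites; geography, duty cycle and effect sizes are the
        defaults.  The cell size still resolves every buffer in the
        1500-21000 m sweep (the smallest buffer always contains a cell
        centre) at ~1/20 of the full-resolution cell count."""
        params = dict(cellsize=0.0125, seed=seed)
        params.update(overrides)
        return cls(**params)


@dataclass
class TruthRecord:
    bird_id: str
    origin: tuple[float, float]
    destination: tuple[float, float]
    start_time: str  # ISO departure from the wintering site
    route_km: float
    stopover_lons: list[float]
    stopover_lats: list[float]
    stopover_days: list[int]
    stopover_scores: list[float]  # standardised cropland scores at the stopovers
    beta_sel: float
    beta_dur: float

    def to_dict(self) -> dict:
        return asdict(self)


_LABEL_TO_CODE = {v: k for k, v in GLOBCOVER_LEGEND.items()}


def _column_weights(cfg: WorldConfig, lons: np.ndarray) -> np.ndarray:
    """Class probability vectors per longitude (n_lons, n_classes).

    The CRO2 weight rises westwards by ``cropland_gradient`` per degree
    (relative to the extent midpoint); the remaining classes share the
    complement in their baseline proportions.
    """
    labels = list(cfg.class_weights)
    base = np.array([cfg.class_weights[l] for l in labels], dtype=float)
    base = base / base.sum()
    mid = 0.5 * (cfg.lon_min + cfg.lon_max)
    out = np.empty((len(lons), len(labels)))
    try:
        i_cro = labels.index("CRO2")
    except ValueError:
        i_cro = None
    for j, lon in enumerate(lons):
        w = base.copy()
        if i_cro is not None and cfg.cropland_gradient != 0.0:
            target = np.clip(base[i_cro] + cfg.cropland_gradient * (mid - lon), 0.0, 1.0)
            others = np.delete(w, i_cro)
            rest = others.sum()
            w[i_cro] = target
            if rest > 0:
                idx = [k for k in range(len(w)) if k != i_cro]
                w[idx] = others * (1.0 - target) / rest
            else:
                w[i_cro] = 1.0
        out[j] = w
    return out


_FOREST_LABELS = ("BFO2", "NFO1", "NFO2", "MFO1")


def generate_raster(cfg: WorldConfig, rng: np.random.Generator | None = None) -> LandCoverRaster:
    """Draw a patchy categorical land-cover raster for the configured extent.

    Two scales of structure: a regional (``region_deg``) cropland-vs-forest
    intensity factor — agricultural regions interleaved with forested ones,
    the dominant compositional axis of European mosaic landscapes — and
    patch-scale (``patch_deg``) categorical mosaic within regions.  On top
    of both, the expected cropland fraction declines west to east.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    labels = list(cfg.class_weights)
    codes = np.array([_LABEL_TO_CODE[l] for l in labels], dtype=np.int16)
    ncols = int(math.ceil((cfg.lon_max - cfg.lon_min) / cfg.cellsize))
    nrows = int(math.ceil((cfg.lat_max - cfg.lat_min) / cfg.cellsize))
    cells_per_patch = max(1, int(round(cfg.patch_deg / cfg.cellsize)))
    pcols = int(math.ceil(ncols / cells_per_patch))
    prows = int(math.ceil(nrows / cells_per_patch))
    patch_lons = cfg.lon_min + (np.arange(pcols) + 0.5) * cells_per_patch * cfg.cellsize
    base = _column_weights(cfg, patch_lons)  # (pcols, n_classes)

    # regional cropland-intensity factor, piecewise constant at region_deg
    patches_per_region = max(1, int(round(cfg.region_deg / (cells_per_patch * cfg.cellsize))))
    rrows = int(math.ceil(prows / patches_per_region))
    rcols = int(math.ceil(pcols / patches_per_region))
    g = rng.normal(0.0, cfg.region_sd, (rrows, rcols))
    g_patch = np.repeat(np.repeat(g, patches_per_region, axis=0), patches_per_region, axis=1)[:prows, :pcols]
    tilt = np.array(
        [1.0 if l in CROPLAND_MOSAIC_LABELS else (-1.0 if l in _FOREST_LABELS else 0.0) for l in labels]
    )
    probs = base[None, :, :] * np.exp(g_patch[:, :, None] * tilt[None, None, :])
    probs = probs / probs.sum(axis=2, keepdims=True)

    cum = np.cumsum(probs, axis=2)
    u = rng.random((prows, pcols))
    idx = (u[:, :, None] > cum[:, :, :-1]).sum(axis=2)
    patch_codes = codes[idx]
    data = np.repeat(np.repeat(patch_codes, cells_per_patch, axis=0), cells_per_patch, axis=1)
    data = data[:nrows, :ncols]
    legend = {c: l for c, l in GLOBCOVER_LEGEND.items() if l in labels}
    return LandCoverRaster(
        data.astype(np.int16), xll=cfg.lon_min, yll=cfg.lat_min, cellsize=cfg.cellsize,
        nodata=DEFAULT_NODATA, legend=legend,
    )


def cropland_fraction(raster: LandCoverRaster, lon: float, lat: float, radius_deg: float) -> float:
    """Cropland + cropland-mosaic fraction (0..1) in a degree buffer."""
    comp = extract_composition(raster, lon, lat, radius_deg, unit="deg")
    code_of = {v: k for k, v in raster.legend.items()}
    return sum(comp.percentages.get(code_of[l], 0.0) for l in CROPLAND_MOSAIC_LABELS if l in code_of) / 100.0


def _softmax_pick(rng: np.random.Generator, logits: np.ndarray, n_pick: int) -> np.ndarray:
    """Sequential weighted sampling without replacement from softmax(logits)."""
    avail = list(range(len(logits)))
    picked = []
    for _ in range(n_pick):
        z = logits[avail] - logits[avail].max()
        w = np.exp(z)
        w = w / w.sum()
        choice = rng.choice(len(avail), p=w)
        picked.append(avail.pop(choice))
    return np.array(sorted(picked), dtype=int)


def simulate_tracks(
    cfg: WorldConfig,
    raster: LandCoverRaster,
    rng: np.random.Generator | None = None,
) -> tuple[list[ArgosFix], list[TruthRecord]]:
    """Simulate every bird's migration and its Argos fix stream.

    Landing candidates are the positions after each full travel day;
    stopovers are drawn among them with log-odds ``beta_sel * score``
    (softmax re-weighting; ``beta_sel = 0`` is uniform).  Fixes are
    emitted only inside duty-cycle "on" windows, each pass succeeding with
    ``pass_success``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    dc = DutyCycle(cfg.duty_off_hours, cfg.duty_on_hours)
    base_date = datetime.fromisoformat(cfg.start_date).replace(tzinfo=timezone.utc)
    fixes: list[ArgosFix] = []
    truths: list[TruthRecord] = []

    for b in range(cfg.n_birds):
        bird_id = f"B{b + 1:02d}"
        lon0 = rng.uniform(cfg.origin_box[0], cfg.origin_box[1])
        lat0 = rng.uniform(cfg.origin_box[2], cfg.origin_box[3])
        lon1 = rng.uniform(cfg.dest_box[0], cfg.dest_box[1])
        lat1 = rng.uniform(cfg.dest_box[2], cfg.dest_box[3])
        if not (raster.xll <= lon1 <= raster.xll + raster.ncols * raster.cellsize
                and raster.yll <= lat1 <= raster.yll + raster.nrows * raster.cellsize):
            raise InvalidConfigError("destination outside raster")
        total_km = float(haversine_km(lon0, lat0, lon1, lat1))
        n_days = max(2, int(math.ceil(total_km / cfg.km_per_day)))
        frac = np.arange(n_days + 1) / n_days
        day_lons = lon0 + frac * (lon1 - lon0)
        day_lats = lat0 + frac * (lat1 - lat0)
        # along-path length: the daily waypoints follow a straight line in
        # lon/lat, which is slightly longer than the great circle
        path_km = float(np.sum(haversine_km(day_lons[:-1], day_lats[:-1], day_lons[1:], day_lats[1:])))

        # candidate landing points: end of each travel day strictly between endpoints
        cand = np.arange(1, n_days)
        raw = np.array([cropland_fraction(raster, day_lons[d], day_lats[d], cfg.score_buffer_deg) for d in cand])
        sd = raw.std()
        scores = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)

        n_stop = min(max(cfg.stopover_min, int(rng.poisson(cfg.stopover_mean))), len(cand))
        chosen = _softmax_pick(rng, cfg.beta_sel * scores, n_stop)  # indices into cand
        chosen_days = cand[chosen]
        durations = []
        for i in chosen:
            ln_d = cfg.duration_log_mean + cfg.beta_dur * scores[i] + rng.normal(0.0, cfg.duration_log_sd)
            durations.append(max(cfg.min_stopover_days, int(round(math.exp(ln_d)))))

        # day-by-day position timeline
        positions: list[tuple[float, float]] = []
        for _ in range(cfg.pre_days):
            positions.append((day_lons[0], day_lats[0]))
        stop_of_day = dict(zip(chosen_days.tolist(), durations))
        for d in range(1, n_days + 1):
            positions.append((day_lons[d], day_lats[d]))
            if d in stop_of_day:
                positions.extend([(day_lons[d], day_lats[d])] * (stop_of_day[d] - 1))
        for _ in range(cfg.post_days):
            positions.append((day_lons[n_days], day_lats[n_days]))

        start = base_date + timedelta(days=int(rng.integers(0, cfg.start_jitter_days + 1)))
        phase_h = float(rng.uniform(0.0, dc.period_hours))
        total_h = len(positions) * 24.0
        t = phase_h
        while t < total_h:
            window_start = t + dc.off_hours
            for j in range(cfg.passes_per_window):
                pass_t = window_start + (j + 0.5) * dc.on_hours / cfg.passes_per_window
                if pass_t >= total_h:
                    break
                if rng.random() >= cfg.pass_success:
                    continue
                day = min(int(pass_t // 24.0), len(positions) - 1)
                plon, plat = positions[day]
                # small within-site movement plus class-dependent Argos noise
                plon += rng.normal(0.0, cfg.local_move_deg)
                plat += rng.normal(0.0, cfg.local_move_deg)
                if rng.random() < cfg.abz_rate:
                    lc = str(rng.choice(["A", "B", "Z"]))
                else:
                    cls = list(cfg.class_probs)
                    pr = np.array([cfg.class_probs[c] for c in cls])
                    lc = str(rng.choice(cls, p=pr / pr.sum()))
                sd_km = cfg.noise_km[lc]
                plat_noise = rng.normal(0.0, sd_km / 111.32)
                plon_noise = rng.normal(0.0, sd_km / (111.32 * max(math.cos(math.radians(plat)), 0.1)))
                fixes.append(
                    ArgosFix(
                        bird_id,
                        start + timedelta(hours=pass_t),
                        float(np.clip(plon + plon_noise, -180.0, 180.0)),
                        float(np.clip(plat + plat_noise, -90.0, 90.0)),
                        lc,
                    )
                )
            t += dc.period_hours

        truths.append(
            TruthRecord(
                bird_id=bird_id,
                origin=(lon0, lat0),
                destination=(lon1, lat1),
                start_time=(start + timedelta(days=cfg.pre_days)).isoformat(),
                route_km=path_km,
                stopover_lons=[float(day_lons[d]) for d in chosen_days],
                stopover_lats=[float(day_lats[d]) for d in chosen_days],
                stopover_days=durations,
                stopover_scores=[float(scores[i]) for i in chosen],
                beta_sel=cfg.beta_sel,
                beta_dur=cfg.beta_dur,
            )
        )

    fixes.sort(key=lambda f: (f.bird_id, f.timestamp))
    return fixes, truths


def write_truth(truths: list[TruthRecord], path: str | Path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in truths], indent=1))


def read_truth(path: str | Path) -> list[TruthRecord]:
    raw = json.loads(Path(path).read_text())
    out = []
    for r in raw:
        r["origin"] = tuple(r["origin"])
        r["destination"] = tuple(r["destination"])
        out.append(TruthRecord(**r))
    return out
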