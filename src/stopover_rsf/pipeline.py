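"""End-to-end orchestration: fixes -> stopovers -> availability ->
compositions -> selection models -> duration correlations -> buffer sweep.

Every stage is a thin wrapper over the library modules; ``run_all`` wires
them together, derives per-stage sub-seeds from one master seed, writes
every table-style CSV plus a JSON run manifest, and returns the results
in memory for programmatic use.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .availability import AvailabilityPoint, build_route, sample_availability
from .habitat import LandCoverRaster, buffer_sweep_radii, composition_table
from .selection_stats import (
    AveragedModel,
    buffer_sweep_models,
    cropland_axis,
    fit_pca,
    replicate_pipeline,
    score,
)
from .duration_stats import correlations_frame, duration_correlations
from .stopover import Site, classify_sites, cluster_sites, sites_to_rows
from .synthetic_world import WorldConfig, generate_raster, simulate_tracks, write_truth
from .telemetry import filter_quality, group_by_bird, read_fixes, write_fixes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and model options; defaults are the study's design values."""

    fixes_path: str = "fixes.csv"
    raster_path: str = "raster.asc"
    legend_path: str = "legend.json"
    out_dir: str = "out"
    # thresholds
    good_classes: tuple[str, ...] = ("0", "1", "2", "3")
    cluster_deg: float = 0.4
    min_stopover_days: float = 2.0
    transect_km: float = 184.0
    buffer_radius: float = 0.2
    buffer_unit: str = "deg"
    n_avail_points: int = 2
    n_replicates: int = 4
    min_sep_deg: float = 0.4
    sweep_min_m: float = 1500.0
    sweep_step_m: float = 1500.0
    sweep_max_m: float = 21000.0
    # model options
    k_pcs: int = 5
    delta_aicc: float = 2.0
    alpha: float = 0.05
    drop_fraction: float = 0.1
    moran_permutations: int = 999
    n_quad: int = 15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.good_classes = tuple(str(c) for c in cfg.good_classes)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["good_classes"] = list(self.good_classes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunResult:
    sites: pd.DataFrame
    stopover_table: pd.DataFrame  # one row per stopover with duration etc.
    availability: pd.DataFrame
    compositions: pd.DataFrame
    pca_loadings: pd.DataFrame
    replicate_models: list[AveragedModel | None]
    global_model: AveragedModel
    moran_traces: list[list[dict]]
    correlations: pd.DataFrame
    sweep: pd.DataFrame
    cropland_pc: str
    cropland_sign: float
    manifest: dict = field(default_factory=dict)


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def detect_stopovers(fixes, cfg: RunConfig):
    """Quality-filter, cluster and classify each bird's fixes.

    A bird's temporally first and last sites are its wintering origin and
    final (breeding-side) position: they anchor the route but are not
    migration stopovers, so they are removed from the stopover list even
    when their occupancy exceeds the duration threshold.
    """
    good = [f for f in filter_quality(fixes) if f.loc_class in cfg.good_classes]
    per_bird = group_by_bird(good)
    all_sites: list[Site] = []
    endpoints: set[int] = set()
    for bird in sorted(per_bird):
        bird_sites = cluster_sites(per_bird[bird], dist_threshold=cfg.cluster_deg)
        if bird_sites:
            endpoints.add(id(bird_sites[0]))
            endpoints.add(id(bird_sites[-1]))
        all_sites.extend(bird_sites)
    stopovers, summary = classify_sites(all_sites, min_stopover_days=cfg.min_stopover_days)
    stopovers = [s for s in stopovers if id(s) not in endpoints]
    return all_sites, stopovers, summary


def sample_all_availability(all_sites: list[Site], stopovers: list[Site], cfg: RunConfig, seed: int):
    """Per-bird routes and replicate availability points for every stopover."""
    rng = np.random.default_rng(seed)
    by_bird: dict[str, list[Site]] = {}
    for s in all_sites:
        by_bird.setdefault(s.bird_id, []).append(s)
    stopover_ids = {id(s): i for i, s in enumerate(stopovers)}
    points: list[AvailabilityPoint] = []
    routes = {}
    for bird in sorted(by_bird):
        sites = by_bird[bird]
        bird_stops = [s for s in sites if id(s) in stopover_ids]
        if not bird_stops:
            continue
        origin = (sites[0].median_lon, sites[0].median_lat)
        terminus = (sites[-1].median_lon, sites[-1].median_lat)
        route = build_route(origin, bird_stops, terminus, bird_id=bird)
        routes[bird] = route
        for s in bird_stops:
            points.extend(
                sample_availability(
                    route, s, stopover_ids[id(s)],
                    n_points=cfg.n_avail_points, n_replicates=cfg.n_replicates,
                    transect_km=cfg.transect_km, min_sep_deg=cfg.min_sep_deg, rng=rng,
                )
            )
    return routes, points


def labelled_points(stopovers: list[Site], avail: list[AvailabilityPoint]) -> list[dict]:
    """Use + availability points in the layout ``composition_table`` expects."""
    pts = [
        {
            "point_id": f"use-{i}",
            "bird_id": s.bird_id,
            "label": "use",
            "replicate": 0,
            "lon": s.median_lon,
            "lat": s.median_lat,
        }
        for i, s in enumerate(stopovers)
    ]
    pts.extend(
        {
            "point_id": f"av-{p.stopover_id}-r{p.replicate}-{p.point_index}",
            "bird_id": p.bird_id,
            "label": "available",
            "replicate": p.replicate,
            "lon": p.lon,
            "lat": p.lat,
        }
        for p in avail
    )
    return pts


def replicate_tables(comp: pd.DataFrame, scores: pd.DataFrame, n_replicates: int) -> list[pd.DataFrame]:
    """Replicate r table = all use rows + replicate-r availability rows."""
    base = pd.concat(
        [comp[["point_id", "bird_id", "label", "replicate", "lon", "lat"]].reset_index(drop=True),
         scores.reset_index(drop=True)],
        axis=1,
    )
    base["y"] = (base["label"] == "use").astype(float)
    tables = []
    for r in range(1, n_replicates + 1):
        tables.append(base[(base["replicate"] == 0) | (base["replicate"] == r)].reset_index(drop=True))
    return tables


def run_all(
    cfg: RunConfig,
    simulate: bool = False,
    world: WorldConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Execute the full analysis; writes CSV outputs and a manifest.

    With ``simulate=True`` a synthetic world (``world`` or the demo
    configuration seeded from the run seed) is generated first and its
    fixes/raster/truth written alongside the analysis outputs.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)

    if simulate:
        wcfg = world if world is not None else WorldConfig.demo(seed=seeds[0])
        rng = np.random.default_rng(wcfg.seed)
        raster = generate_raster(wcfg, rng)
        fixes, truths = simulate_tracks(wcfg, raster, rng)
        write_fixes(fixes, out / "fixes.csv")
        raster.write_ascii(out / "raster.asc", out / "legend.json")
        write_truth(truths, out / "truth.json")
    else:
        if not Path(cfg.fixes_path).exists():
            raise FileNotFoundError(f"fixes file {cfg.fixes_path} not found (use --simulate to generate)")
        if not Path(cfg.raster_path).exists():
            raise FileNotFoundError(f"raster file {cfg.raster_path} not found (use --simulate to generate)")
        fixes = read_fixes(cfg.fixes_path)
        legend = cfg.legend_path if Path(cfg.legend_path).exists() else None
        raster = LandCoverRaster.read_ascii(cfg.raster_path, legend)

    # stopover detection
    all_sites, stopovers, summary = detect_stopovers(fixes, cfg)
    sites_df = pd.DataFrame(sites_to_rows(all_sites))
    sites_df.to_csv(out / "sites.csv", index=False)
    if len(stopovers) < cfg.k_pcs + 1:
        raise RuntimeError(f"only {len(stopovers)} stopovers detected; too few to model")

    # availability sampling
    routes, avail = sample_all_availability(all_sites, stopovers, cfg, seeds[1])
    avail_df = pd.DataFrame(
        [
            {
                "bird_id": p.bird_id, "stopover_id": p.stopover_id, "replicate": p.replicate,
                "point_index": p.point_index, "lon": p.lon, "lat": p.lat, "offset_km": p.offset_km,
            }
            for p in avail
        ]
    )
    avail_df.to_csv(out / "availability.csv", index=False)

    # compositions at the primary buffer + PCA over all four replicates
    pts = labelled_points(stopovers, avail)
    comp = composition_table(pts, raster, cfg.buffer_radius, cfg.buffer_unit)
    comp.to_csv(out / "compositions.csv", index=False)
    pc = fit_pca(comp, k=cfg.k_pcs)
    loadings = pc.loadings_frame()
    extra = pd.DataFrame(
        [pc.eigenvalues[: pc.k], pc.variance_fractions[: pc.k] * 100.0],
        index=["eigenvalue", "variance_pct"], columns=loadings.columns,
    )
    pd.concat([loadings, extra]).to_csv(out / "pca_loadings.csv")
    scores = score(pc, comp)
    crop_pc, crop_sign = cropland_axis(pc)

    # per-replicate decorrelation + dredge averaging, then the global model
    tables = replicate_tables(comp, scores, cfg.n_replicates)
    rep_models, global_model, traces = replicate_pipeline(
        tables, pc.component_names, delta=cfg.delta_aicc, alpha=cfg.alpha,
        drop_fraction=cfg.drop_fraction, rng=seeds[2], n_perm=cfg.moran_permutations,
        n_quad=cfg.n_quad,
    )
    for i, m in enumerate(rep_models, start=1):
        if m is not None:
            m.table().to_csv(out / f"averaged_model_rep{i}.csv", index=False)
    global_model.table().to_csv(out / "averaged_model_global.csv", index=False)
    (out / "moran_trace.json").write_text(json.dumps(traces, indent=1))

    # duration and longitude correlations at the primary buffer
    use_rows = comp[comp["label"] == "use"].reset_index(drop=True)
    use_scores = score(pc, use_rows)
    durations = np.array([s.duration_days for s in stopovers])
    longitudes = use_rows["lon"].to_numpy()
    corr = correlations_frame(duration_correlations(durations, longitudes, use_scores))
    corr.to_csv(out / "duration_correlations.csv", index=False)

    # buffer-size sensitivity sweep on replicate-1 points
    radii = buffer_sweep_radii(cfg.sweep_min_m, cfg.sweep_step_m, cfg.sweep_max_m)
    rep1_pts = [p for p in pts if p["replicate"] in (0, 1)]
    sweep = buffer_sweep_models(rep1_pts, raster, radii, k_pcs=cfg.k_pcs, n_quad=cfg.n_quad)
    sweep.to_csv(out / "buffer_sweep.csv", index=False)

    stop_table = pd.DataFrame(
        {
            "bird_id": [s.bird_id for s in stopovers],
            "lon": [s.median_lon for s in stopovers],
            "lat": [s.median_lat for s in stopovers],
            "duration_days": durations,
        }
    )
    stop_table.to_csv(out / "stopovers.csv", index=False)

    cfg_dict = asdict(cfg)
    cfg_dict["good_classes"] = list(cfg.good_classes)
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16],
        "seed": cfg.seed,
        "simulated": simulate,
        "n_fixes": len(fixes),
        "n_sites": len(all_sites),
        "n_stopovers": len(stopovers),
        "n_availability_points": len(avail),
        "site_summary": summary.counts,
        "cropland_pc": crop_pc,
        "cropland_sign": crop_sign,
        "replicate_failures": global_model.failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return RunResult(
        sites=sites_df,
        stopover_table=stop_table,
        availability=avail_df,
        compositions=comp,
        pca_loadings=loadings,
        replicate_models=rep_models,
        global_model=global_model,
        moran_traces=traces,
        correlations=corr,
        sweep=sweep,
        cropland_pc=crop_pc,
        cropland_sign=crop_sign,
        manifest=manifest,
    )
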