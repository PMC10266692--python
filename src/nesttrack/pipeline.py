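"""End-to-end orchestration: filter -> regularize -> segment -> nests ->
space use -> coverage -> migration -> effort overlap.

`run_cohort` drives the whole analysis from in-memory inputs and returns a
per-animal report table (one row per animal, Table-1-style), the cohort
summary (mean +/- sample sd of each numeric column) and all intermediate
stage artifacts.  `run` is the file-based wrapper the CLI uses.  Animals
that fail a stage are skipped with a logged reason, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coverage as cov
from . import migration as mig
from . import nesting, segmentation
from .io_formats import (NamedRegionSet, format_date, read_argos_csv,
                         read_drytime_csv, read_effort_csv, read_regions)
from .nesting import NestingConfig, cohort_stats
from .preprocessing import FilterConfig, apply_filters, filter_on_land, regularize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    nesting: NestingConfig = field(default_factory=NestingConfig)
    delta_internesting: str = "4h"
    delta_migration: str = "1D"
    lmin_points: int = 3            # 12 h at the 4-h interval
    kmax: int = 6
    period_days: float = 11.5       # inter-nesting cycle for the movement models
    period_days_overrides: dict = field(default_factory=dict)
    group_threshold_km: float = mig.GROUP_THRESHOLD_KM
    buffer_distances_km: tuple = cov.DEFAULT_BUFFERS_KM
    ud_resolution_km: float = 1.0
    fit_space_use: bool = True
    error_sds_per_class: dict | None = None


@dataclass
class AnimalResult:
    animal_id: str
    report: dict
    events: list = field(default_factory=list)
    onset: object = None
    track_4h: object = None
    internesting_track: object = None
    daily_track: object = None
    ud: object = None
    fit: object = None
    migration: object = None
    error: str | None = None


def _analyse_animal(animal_id, locs, timeline, regions: NamedRegionSet,
                    cfg: PipelineConfig) -> AnimalResult:
    land = regions.by_kind("land")[0].geometry
    beach_regions = regions.by_kind("beach")
    beach = beach_regions[0].geometry if beach_regions else land
    tagging_time = locs["timestamp"].iloc[0]

    # pass 1: class/speed filters, provisional land filter over the full
    # range (migration onset unknown until segmentation)
    base = apply_filters(locs, cfg.filter)
    pass1 = filter_on_land(base, land, None)
    track = regularize(pass1, cfg.delta_internesting, cfg.error_sds_per_class)
    origin = (float(locs["lon"].iloc[0]), float(locs["lat"].iloc[0]))
    disp = segmentation.displacement(track, origin)
    seg = segmentation.lavielle_segment(disp["d_km"].to_numpy(),
                                        lmin=cfg.lmin_points, kmax=cfg.kmax)
    onset = segmentation.migration_start(seg, disp)
    logger.info("segment %s: K=%d status=%s", animal_id, seg.K, onset.status)

    # pass 2: land filter scoped to the inter-nesting window
    if onset.status != "never_migrated":
        scoped = filter_on_land(base, land, (tagging_time, onset.time))
        track = regularize(scoped, cfg.delta_internesting,
                           cfg.error_sds_per_class)
        disp = segmentation.displacement(track, origin)

    events = nesting.detect_attempts(timeline, cfg.nesting)
    events = nesting.confirm_on_land(events, locs, land, beach, cfg.nesting)
    events = nesting.classify_attempts(events, cfg.nesting, timeline)
    migration_time = onset.time if onset.status != "never_migrated" else None
    nest_sum = nesting.nesting_summary(events, tagging_time, migration_time)
    logger.info("nests %s: %d attempts, %d successful", animal_id,
                nest_sum["attempts"], nest_sum["successful_clutches"])

    internesting = (track.slice_time(end=migration_time)
                    if migration_time is not None else track)
    ud = fit = None
    if cfg.fit_space_use and len(internesting.times) >= 20:
        from . import space_use
        period = cfg.period_days_overrides.get(animal_id, cfg.period_days)
        fits = space_use.fit_models(internesting, period_days=period)
        fit = space_use.select_model(fits)
        ud = space_use.estimate_ud(internesting, fit,
                                   grid_resolution_km=cfg.ud_resolution_km,
                                   check_refinement=False)
        logger.info("space_use %s: %s%s n_eff=%.1f", animal_id, fit.model,
                    "+periodic" if fit.periodic else "", fit.n_eff())

    msum = daily = None
    if migration_time is not None:
        scoped = filter_on_land(base, land, (tagging_time, migration_time))
        daily_full = regularize(scoped, cfg.delta_migration,
                                cfg.error_sds_per_class)
        daily = daily_full.slice_time(start=migration_time)
        if len(daily.times) >= 2:
            msum = mig.migration_summary(daily, migration_time, origin=origin,
                                         threshold_km=cfg.group_threshold_km)

    deployment = nesting.whole_days(tagging_time, locs["timestamp"].iloc[-1])
    report = {
        "animal_id": animal_id,
        "tag_date": format_date(tagging_time),
        "migration_start": (format_date(migration_time)
                            if migration_time is not None else "NA"),
        "observed_nesting_duration_days": nest_sum["observed_nesting_duration_days"],
        "estimated_nesting_attempts": nest_sum["attempts"],
        "successful_clutches": nest_sum["successful_clutches"],
        "migration_group": msum.group if msum else "NA",
        "migration_duration_days": msum.duration_days if msum else None,
        "final_displacement_km": (round(msum.final_displacement_km)
                                  if msum else None),
        "total_distance_km": (round(msum.total_path_km) if msum else None),
        "deployment_duration_days": deployment,
    }
    return AnimalResult(animal_id=animal_id, report=report, events=events,
                        onset=onset, track_4h=track,
                        internesting_track=internesting, daily_track=daily,
                        ud=ud, fit=fit, migration=msum)


def run_cohort(argos: pd.DataFrame, drytime: pd.DataFrame,
               regions: NamedRegionSet, cfg: PipelineConfig | None = None,
               effort=None):
    """Run the full analysis on in-memory inputs.

    Returns (report DataFrame, cohort-summary DataFrame, dict of artifacts).
    Per-animal failures skip the animal with a logged reason.
    """
    cfg = cfg or PipelineConfig()
    results, skipped = [], []
    for animal_id, locs in argos.groupby("animal_id", sort=True):
        tl = drytime[drytime["animal_id"] == animal_id]
        if len(tl) == 0:
            skipped.append((animal_id, "no dry-time timeline"))
            continue
        try:
            results.append(_analyse_animal(str(animal_id),
                                           locs.reset_index(drop=True), tl,
                                           regions, cfg))
        except Exception as exc:      # per-animal isolation
            logger.warning("skipping %s: %s", animal_id, exc)
            skipped.append((animal_id, str(exc)))
    report = pd.DataFrame([r.report for r in results])

    summary_rows = []
    if len(report):
        for col in ("observed_nesting_duration_days", "estimated_nesting_attempts",
                    "successful_clutches", "migration_duration_days",
                    "final_displacement_km", "total_distance_km",
                    "deployment_duration_days"):
            m, s = cohort_stats(report[col].dropna().tolist())
            summary_rows.append({"metric": col, "mean": m, "sd": s})
        pooled = np.concatenate([nesting.emergence_intervals(r.events)
                                 for r in results]) if results else np.array([])
        if len(pooled):
            summary_rows.append({"metric": "internesting_interval_days",
                                 "mean": float(pooled.mean()),
                                 "sd": float(pooled.std(ddof=1))
                                 if len(pooled) > 1 else np.nan})
    summary = pd.DataFrame(summary_rows)

    artifacts = {"results": results, "skipped": skipped}

    # coverage / residency on the animals with inter-nesting data
    inter_tracks = [r.internesting_track for r in results
                    if r.internesting_track is not None
                    and len(r.internesting_track.times) > 0]
    cores = [r.ud.contours[0.5]["polygons"] for r in results if r.ud is not None]
    reserve = regions.by_kind("reserve")
    if inter_tracks and reserve:
        scenario = cov.BufferScenario(reserve=reserve[0].geometry,
                                      coast=regions.by_kind("land")[0].geometry,
                                      distances_km=cfg.buffer_distances_km)
        artifacts["coverage"] = cov.coverage_report(inter_tracks, cores, scenario)
        artifacts["reserve_pct_time"] = {
            tr.animal_id: cov.time_in_region(tr, reserve[0].geometry)
            for tr in inter_tracks}
    daily_tracks = [r.daily_track for r in results
                    if r.daily_track is not None and len(r.daily_track.times) > 0]
    if daily_tracks:
        artifacts["eez_residency"] = cov.eez_residency(daily_tracks, regions)
    if effort is not None and daily_tracks:
        lt = mig.longterm_mean(mig.regrid_effort(effort, 0.5))
        artifacts["effort_longterm"] = lt
        artifacts["overlap"] = [mig.track_effort_overlap(tr, lt)
                                for tr in daily_tracks]
    return report, summary, artifacts


def run(argos_path, drytime_path, regions_path, effort_path=None,
        cfg: PipelineConfig | None = None):
    """File-based entry point (CSV/GeoJSON in, DataFrames out)."""
    argos = read_argos_csv(argos_path)
    drytime = read_drytime_csv(drytime_path)
    regions = read_regions(regions_path)
    effort = read_effort_csv(effort_path) if effort_path else None
    return run_cohort(argos, drytime, regions, cfg, effort)
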