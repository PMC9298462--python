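"""End-to-end pipeline: simulate/ingest -> localize -> prep -> home range ->
features -> cluster, with per-stage outputs and a reproducibility manifest.

Each stage is an importable function over plain containers so the numbered
analysis drivers, the tests, and the acceptance script all run the same
code. ``run_pipeline`` chains the stages; rerunning with the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    ClassOccupancy,
    ClusterResult,
    class_occupancy,
    agglomerate,
    cut_by_merger_score,
    fit_pca,
    label_classes,
    merge_classes,
)
from .config import PipelineConfig
from .features import FEATURE_NAMES, feature_table, global_center, normalize_features, segment_daily
from .homerange import boundary_polygon, occupancy_map, range_stability, sleeping_site_summary
from .localize import fit_clock_model, localize_all
from .prep import DayWindow, RegularTrajectory, contiguous_days, interpolate_to_minutes, select_qc_days
from .simulate import (
    SimulationConfig,
    TrueTrajectory,
    build_triangular_array,
    simulate_beacon_detections,
    simulate_detections,
    simulate_trajectory,
)

logger = logging.getLogger("reeftrack")

SECONDS_PER_DAY = 86400.0


@dataclass
class SimulatedDataset:
    """Everything stage 1 produces: truth, array, and detection logs."""

    array: "ReceiverArraySpec"
    trajectories: dict[str, TrueTrajectory]
    detections: pd.DataFrame
    beacon_detections: pd.DataFrame
    emissions: dict[str, pd.DataFrame]
    day_window: tuple[int, int]


def stage_simulate(config: PipelineConfig) -> SimulatedDataset:
    """Simulate the fish, the receiver array, and all detection logs."""
    sim = config.simulation
    arr = config.array
    ss = np.random.SeedSequence(config.seed)
    fish_seeds = ss.spawn(sim.n_fish + 2)

    cx, cy = sim.home_center
    hx, hy = sim.home_extent[0] / 2, sim.home_extent[1] / 2
    m = arr.margin_m
    array = build_triangular_array(
        (cx - hx - m, cy - hy - m, cx + hx + m, cy + hy + m),
        spacing=arr.spacing_m,
        beacon_every=arr.beacon_every,
        detection_range=arr.detection_range_m,
        timing_noise_sd=arr.timing_noise_sd_s,
    )
    clock_rng = np.random.default_rng(fish_seeds[-1])
    array = array.with_clock_errors(clock_rng, arr.clock_offset_sd_s, arr.clock_drift_sd)

    p = np.full((4, 4), (1.0 - sim.mode_self_transition) / 3.0)
    np.fill_diagonal(p, sim.mode_self_transition)

    trajectories: dict[str, TrueTrajectory] = {}
    emissions: dict[str, pd.DataFrame] = {}
    det_frames = []
    for i in range(sim.n_fish):
        fish = f"F{i + 1}"
        seeds = fish_seeds[i].generate_state(2)
        sc = SimulationConfig(
            home_center=sim.home_center,
            home_extent=sim.home_extent,
            sleep_site=sim.sleep_site,
            n_days=sim.n_days,
            mode_transition_matrix=p,
            day_window=sim.day_window,
            transmission_interval=sim.transmission_interval_s,
            rng_seed=int(seeds[0] % (2**31)),
        )
        traj = simulate_trajectory(sc)
        trajectories[fish] = traj
        log = simulate_detections(
            traj,
            array,
            seed=int(seeds[1] % (2**31)),
            tag_id=fish,
            transmission_interval=sim.transmission_interval_s,
            night_dropout=sim.night_dropout,
            speed_of_sound=config.localization.speed_of_sound_m_s,
        )
        det_frames.append(log.detections.drop(columns=["emission_index"]))
        emissions[fish] = log.emissions
    duration = sim.n_days * SECONDS_PER_DAY
    beacon_det = simulate_beacon_detections(
        array,
        duration,
        seed=int(fish_seeds[-2].generate_state(1)[0] % (2**31)),
        transmission_interval=30.0,
        speed_of_sound=config.localization.speed_of_sound_m_s,
    )
    detections = pd.concat(det_frames, ignore_index=True).sort_values("arrival_time_s").reset_index(drop=True)
    logger.info(
        "simulated %d fish x %d days: %d tag detections, %d beacon detections",
        sim.n_fish, sim.n_days, len(detections), len(beacon_det),
    )
    return SimulatedDataset(
        array=array,
        trajectories=trajectories,
        detections=detections,
        beacon_detections=beacon_det,
        emissions=emissions,
        day_window=sim.day_window,
    )


def stage_localize(data: SimulatedDataset, config: PipelineConfig) -> pd.DataFrame:
    """Clock-correct and localize every transmission heard by >= 3 receivers."""
    loc = config.localization
    clock = fit_clock_model(
        data.beacon_detections,
        data.array.sync_beacons,
        data.array.stations,
        window_s=loc.sync_window_s,
        speed_of_sound=loc.speed_of_sound_m_s,
    )
    fixes = localize_all(
        data.detections,
        data.array,
        clock=clock,
        grid_spacing=loc.grid_spacing_m,
        inflate=loc.grid_inflate_m,
        speed_of_sound=loc.speed_of_sound_m_s,
    )
    logger.info("localized %d fixes from %d detections", len(fixes), len(data.detections))
    return fixes


def day_windows_for(config: PipelineConfig, n_days: int) -> dict[int, DayWindow]:
    """Per-day daytime windows (simulated time uses the configured window)."""
    sr, ss = config.simulation.day_window
    return {d: DayWindow(d, float(sr), float(ss)) for d in range(n_days)}


@dataclass
class PreparedData:
    windows: dict[int, DayWindow]
    qc_runs: dict[str, list[list[int]]]
    trajectories: dict[str, dict[int, RegularTrajectory]]  # fish -> day -> traj


def stage_prep(fixes: pd.DataFrame, config: PipelineConfig, n_days: int) -> PreparedData:
    """QC-select days and interpolate each accepted day to the 1-min grid."""
    windows = day_windows_for(config, n_days)
    qc_runs: dict[str, list[list[int]]] = {}
    trajectories: dict[str, dict[int, RegularTrajectory]] = {}
    for fish, sub in fixes.groupby("tag_id"):
        runs = select_qc_days(sub.rename(columns={"time_s": "time_s"}), windows, config.prep.min_per_hour)
        qc_runs[str(fish)] = runs
        accepted = contiguous_days(runs, config.prep.min_run_days)
        per_day = {}
        for day in accepted:
            day_fixes = sub[(sub["time_s"] >= day * SECONDS_PER_DAY) & (sub["time_s"] < (day + 1) * SECONDS_PER_DAY)]
            traj = interpolate_to_minutes(day_fixes, windows[day], day=day, fish_id=str(fish))
            if traj is not None:
                per_day[day] = traj
        trajectories[str(fish)] = per_day
        logger.info("fish %s: %d/%d days pass QC", fish, len(per_day), n_days)
    return PreparedData(windows=windows, qc_runs=qc_runs, trajectories=trajectories)


@dataclass
class HomeRangeSummary:
    boundaries: dict[str, "HomeRangePolygon"]
    occupancy: dict[str, "OccupancyGrid"]
    stability_iou: dict[str, float]
    sleeping_sites: dict[str, dict]


def stage_homerange(fixes: pd.DataFrame, prepared: PreparedData, config: PipelineConfig) -> HomeRangeSummary:
    """Boundary, occupancy, first-vs-last-days stability, sleeping sites."""
    hr = config.homerange
    boundaries, occ, stab, sleep = {}, {}, {}, {}
    for fish, per_day in prepared.trajectories.items():
        sub = fixes[fixes["tag_id"] == fish]
        pts = sub[["x_m", "y_m"]].to_numpy(dtype=float)
        if len(pts) >= 3:
            boundaries[fish] = boundary_polygon(pts, hr.shrink_factor)
        if per_day:
            xy = np.vstack([t.xy for t in per_day.values()])
            occ[fish] = occupancy_map(xy, hr.occupancy_bin_m, hr.occupancy_sigma_m)
            day_pts = {d: t.xy for d, t in per_day.items()}
            if len(day_pts) >= 2 * hr.stability_k_days:
                _, _, iou = range_stability(day_pts, hr.stability_k_days, hr.stability_k_days, hr.shrink_factor)
                stab[fish] = iou
        sr, ss = config.simulation.day_window
        mod = (sub["time_s"].to_numpy(dtype=float) % SECONDS_PER_DAY) / 60.0
        night = sub[(mod < sr) | (mod >= ss)]
        if len(night):
            sleep[fish] = sleeping_site_summary(night[["x_m", "y_m"]].to_numpy(dtype=float))
    return HomeRangeSummary(boundaries=boundaries, occupancy=occ, stability_iou=stab, sleeping_sites=sleep)


def stage_features(prepared: PreparedData, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Per-fish segment feature tables (unscaled)."""
    fc = config.features
    out: dict[str, pd.DataFrame] = {}
    for fish, per_day in prepared.trajectories.items():
        segs = []
        for day in sorted(per_day):
            segs.extend(segment_daily(per_day[day], fc.segment_length_min, fc.overlap))
        if not segs:
            continue
        all_xy = np.vstack([t.xy for t in per_day.values()])
        out[fish] = feature_table(segs, global_center(all_xy), prepared.windows)
        logger.info("fish %s: %d segments", fish, len(segs))
    return out


@dataclass
class ClusteringSummary:
    pca: dict[str, "PCAModel"]
    results: dict[str, ClusterResult]
    labels: pd.DataFrame  # fish_id, day, start_min, class
    occupancy: dict[str, ClassOccupancy]


def stage_cluster(features: dict[str, pd.DataFrame], prepared: PreparedData, config: PipelineConfig) -> ClusteringSummary:
    """Per-fish PCA, agglomerative clustering, merger-score cut, labeling."""
    cc = config.clustering
    pca_models, results, label_rows, occ = {}, {}, [], {}
    for fish, table in features.items():
        scaled, _, _ = normalize_features(table)
        model, scores = fit_pca(scaled[list(FEATURE_NAMES)].to_numpy(), k=cc.n_components)
        tree = agglomerate(scores, cc.linkage_method)
        result = cut_by_merger_score(tree, cc.threshold)
        if cc.merge_pairs:
            result = merge_classes(result, cc.merge_pairs)
        result = label_classes(result, table)
        pca_models[fish] = model
        results[fish] = result
        lab = table[["fish_id", "day", "start_min"]].copy()
        lab["class"] = result.named_labels()
        label_rows.append(lab)
        occ[fish] = class_occupancy(lab, prepared.windows, config.features.segment_length_min)
        logger.info(
            "fish %s: %d classes (sensitivity %s), %.0f%% variance in %d PCs",
            fish, result.n_classes, result.sensitivity, 100 * model.selected_variance, model.k,
        )
    labels = pd.concat(label_rows, ignore_index=True) if label_rows else pd.DataFrame()
    return ClusteringSummary(pca=pca_models, results=results, labels=labels, occupancy=occ)


@dataclass
class PipelineResult:
    config: PipelineConfig
    data: SimulatedDataset
    fixes: pd.DataFrame
    prepared: PreparedData
    homerange: HomeRangeSummary
    features: dict[str, pd.DataFrame]
    clustering: ClusteringSummary
    manifest: dict = field(default_factory=dict)


STAGES = ("simulate", "localize", "prep", "homerange", "features", "cluster")


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run all stages in order; optionally write stage outputs + manifest."""
    if config.mode != "simulate":
        raise NotImplementedError("ingest mode requires pre-recorded CSVs; see analysis drivers")
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "stages": {},
    }
    stage_outputs: dict[str, list[str]] = {}
    try:
        data = stage_simulate(config)
        stage_outputs["simulate"] = ["stations.csv", "beacons.csv", "detections.csv", "true_trajectories.csv"]
        fixes = stage_localize(data, config)
        stage_outputs["localize"] = ["fixes.csv"]
        prepared = stage_prep(fixes, config, config.simulation.n_days)
        stage_outputs["prep"] = ["trajectories.csv"]
        hr = stage_homerange(fixes, prepared, config)
        stage_outputs["homerange"] = ["homerange.geojson", "sleeping_sites.csv"]
        feats = stage_features(prepared, config)
        stage_outputs["features"] = ["features.csv"]
        clust = stage_cluster(feats, prepared, config)
        stage_outputs["cluster"] = ["labels.csv", "pca_report.csv", "class_occupancy.csv"]
    except Exception as exc:
        manifest["stages"] = stage_outputs
        manifest["failed_stage"] = STAGES[len(stage_outputs)] if len(stage_outputs) < len(STAGES) else "unknown"
        if out_dir is not None:
            _write_manifest(Path(out_dir), manifest)
        raise RuntimeError(f"pipeline failed in stage '{manifest['failed_stage']}'") from exc

    manifest["stages"] = stage_outputs
    result = PipelineResult(config, data, fixes, prepared, hr, feats, clust, manifest)
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def _write_manifest(out: Path, manifest: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def write_outputs(result: PipelineResult, out: Path) -> None:
    """Write every stage's tabular outputs plus the manifest."""
    out.mkdir(parents=True, exist_ok=True)
    data = result.data
    data.array.stations.to_csv(out / "stations.csv", index=False)
    data.array.sync_beacons.to_csv(out / "beacons.csv", index=False)
    data.detections.to_csv(out / "detections.csv", index=False)
    pd.concat(
        [t.to_frame().assign(fish_id=f) for f, t in data.trajectories.items()], ignore_index=True
    ).to_csv(out / "true_trajectories.csv", index=False)
    result.fixes.to_csv(out / "fixes.csv", index=False)
    trajs = [
        t.to_frame() for per_day in result.prepared.trajectories.values() for t in per_day.values()
    ]
    if trajs:
        pd.concat(trajs, ignore_index=True).to_csv(out / "trajectories.csv", index=False)
    geo = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": b.geometry.__geo_interface__,
                "properties": {"fish_id": f, "area_m2": b.area, "shrink_factor": b.shrink_factor,
                               "crs": "local metric (m)", "schema_version": 1},
            }
            for f, b in result.homerange.boundaries.items()
        ],
    }
    with open(out / "homerange.geojson", "w") as fh:
        json.dump(geo, fh)
    if result.homerange.sleeping_sites:
        pd.DataFrame(
            [{"fish_id": f, **s} for f, s in result.homerange.sleeping_sites.items()]
        ).to_csv(out / "sleeping_sites.csv", index=False)
    if result.features:
        pd.concat(result.features.values(), ignore_index=True).to_csv(out / "features.csv", index=False)
    if len(result.clustering.labels):
        result.clustering.labels.to_csv(out / "labels.csv", index=False)
        pca_rows = []
        for f, m in result.clustering.pca.items():
            for i in range(m.k):
                pca_rows.append(
                    {"fish_id": f, "component": i + 1, "variance_fraction": m.variance_fractions[i],
                     **{name: m.loadings[i, j] for j, name in enumerate(FEATURE_NAMES)}}
                )
        pd.DataFrame(pca_rows).to_csv(out / "pca_report.csv", index=False)
        pd.concat(
            [o.fractions for o in result.clustering.occupancy.values()]
        ).to_csv(out / "class_occupancy.csv")
    _write_manifest(out, result.manifest)
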