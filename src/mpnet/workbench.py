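"""Seeded experiment orchestration: staged runs with on-disk artifacts.

``run_experiment`` wires the construction, protocol, analysis and
mean-field modules into reproducible pipelines.  Every stage reads its
inputs from and writes its outputs to the experiment directory, so any
downstream analysis can be recomputed from saved artifacts alone, and a
manifest records the configuration hash, seed substreams and the file
inventory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis, io, meanfield
from .config import ExperimentConfig, config_hash, save_config
from .construction import (ClusterMap, WeightMatrix, assign_clusters,
                           build_connectivity)
from .protocols import (make_perturbation_schedule, make_training_schedule,
                        run_session, StimulusSchedule)

__all__ = ["RunManifest", "run_experiment", "STAGES"]

log = logging.getLogger("mpnet")

STAGES = ("build", "train", "ongoing", "perturb", "analyze", "meanfield")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    completed: list[str] = field(default_factory=list)
    outputs: dict[str, list[str]] = field(default_factory=dict)
    wall_time_s: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
        tmp.replace(path)  # atomic on POSIX


def _save_cluster_map(path: Path, cm: ClusterMap) -> None:
    np.savez_compressed(path, eta=cm.eta)


def _load_cluster_map(path: Path) -> ClusterMap:
    with np.load(path) as z:
        return ClusterMap(z["eta"].copy())


def _session_outputs(out: Path, tag: str, cfg: ExperimentConfig,
                     weights: WeightMatrix, rec) -> list[str]:
    files = []
    spikes = out / f"{tag}_spikes.txt"
    io.write_spike_table(spikes, rec.spike_times, rec.spike_ids,
                         N=rec.N, N_E=rec.N_E, dt=rec.dt, seed=cfg.seed)
    files.append(spikes.name)
    wpath = out / f"{tag}_weights.npz"
    io.write_weight_snapshot(wpath, weights, seed=cfg.seed)
    files.append(wpath.name)
    if rec.class_times is not None:
        cpath = out / f"{tag}_weight_classes.csv"
        np.savetxt(cpath,
                   np.column_stack([rec.class_times, rec.w0, rec.w1]),
                   header="t_ms w0 w1", comments="# ")
        files.append(cpath.name)
    return files


def run_experiment(cfg: ExperimentConfig, stages: list[str],
                   out_dir: str | Path,
                   perturb_scenario: str = "random",
                   ongoing_ms: float = 600_000.0,
                   plasticity_on: bool = True) -> RunManifest:
    """Execute pipeline stages in order, wiring outputs to inputs.

    Artifacts are read back from ``out_dir`` when a stage depends on one
    that ran in an earlier invocation, so pipelines can be resumed.
    """
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), seed=cfg.seed,
                           stages=list(stages))
    save_config(cfg, out / "config.yaml")

    weights: WeightMatrix | None = None
    cluster_map: ClusterMap | None = None
    last_state = None
    last_ps = None

    def need_build():
        nonlocal weights, cluster_map
        if weights is None:
            wpath = out / "build_weights.npz"
            cpath = out / "build_clusters.npz"
            if wpath.exists() and cpath.exists():
                weights, _ = io.read_weight_snapshot(wpath)
                cluster_map = _load_cluster_map(cpath)
            else:
                raise RuntimeError("stage requires 'build' to have run")

    for st in stages:
        t0 = time.monotonic()
        log.info("stage %s starting", st)
        if st == "build":
            weights = build_connectivity(cfg.network)
            cluster_map = assign_clusters(cfg.network.N_E, cfg.network.Q,
                                          cfg.network.f, cfg.network.seed)
            io.write_weight_snapshot(out / "build_weights.npz", weights,
                                     seed=cfg.seed)
            _save_cluster_map(out / "build_clusters.npz", cluster_map)
            stats = cluster_map.stats()
            (out / "build_cluster_stats.json").write_text(
                json.dumps(stats, indent=2))
            manifest.outputs[st] = ["build_weights.npz",
                                    "build_clusters.npz",
                                    "build_cluster_stats.json"]
        elif st == "train":
            need_build()
            schedule = make_training_schedule(
                cluster_map, cfg.training_session_ms,
                period_ms=cfg.train_period_ms, stim_ms=cfg.train_stim_ms,
                amplitude=cfg.network.h_st, seed=cfg.seed,
                random_intervals=cfg.train_random_intervals)
            weights, rec = run_session(weights, schedule, cfg,
                                       cluster_map=cluster_map,
                                       plasticity_on=plasticity_on)
            last_state, last_ps = rec.final_state, rec.final_plasticity
            manifest.outputs[st] = _session_outputs(out, "train", cfg,
                                                    weights, rec)
        elif st in ("ongoing", "perturb"):
            need_build()
            if st == "ongoing":
                schedule = StimulusSchedule([], ongoing_ms, scenario="none")
            else:
                set2 = (ClusterMap(
                    assign_clusters(cfg.network.N_E, cfg.network.Q,
                                    cfg.network.f,
                                    cfg.seed + 1).eta)
                    if perturb_scenario in ("mixed", "novel") else None)
                schedule = make_perturbation_schedule(
                    perturb_scenario, ongoing_ms,
                    mean_interval_ms=cfg.perturb_mean_interval_ms,
                    stim_ms=cfg.perturb_stim_ms, set2=set2,
                    N_E=cfg.network.N_E, f=cfg.network.f,
                    amplitude=cfg.network.h_st, seed=cfg.seed)
            weights, rec = run_session(weights, schedule, cfg,
                                       cluster_map=cluster_map,
                                       plasticity_on=plasticity_on,
                                       initial_state=last_state,
                                       initial_plasticity=last_ps)
            last_state, last_ps = rec.final_state, rec.final_plasticity
            manifest.outputs[st] = _session_outputs(out, st, cfg,
                                                    weights, rec)
        elif st == "analyze":
            need_build()
            report = {}
            files = []
            for tag in ("train", "ongoing", "perturb"):
                spath = out / f"{tag}_spikes.txt"
                if not spath.exists():
                    continue
                times, ids, _ = io.read_spike_table(spath)
                ov = analysis.overlaps_from_spikes(
                    times, ids, cluster_map,
                    window_ms=cfg.rate_window_ms, grid_ms=cfg.rate_grid_ms)
                segments = analysis.detect_states(ov)
                seg_path = out / f"{tag}_states.csv"
                analysis.segments_to_frame(segments).to_csv(seg_path,
                                                            index=False)
                files.append(seg_path.name)
                stats = analysis.duration_stats(segments)
                report[tag] = {
                    "n_segments": stats["n"],
                    "mean_duration_ms": stats["mean_ms"],
                    "sd_duration_ms": stats["sd_ms"],
                    "exponentiality": stats["exponentiality"],
                }
                cls_path = out / f"{tag}_weight_classes.csv"
                if cls_path.exists():
                    arr = np.loadtxt(cls_path)
                    report[tag]["w0_final"] = float(arr[-1, 1])
                    report[tag]["w1_final"] = float(arr[-1, 2])
            (out / "analysis_report.json").write_text(
                json.dumps(report, indent=2))
            files.append("analysis_report.json")
            manifest.outputs[st] = files
        elif st == "meanfield":
            mf = meanfield.MeanFieldConfig(neuron=cfg.neuron)
            mu_grid = np.linspace(0.1, 1.5, 15)
            sig_grid = np.linspace(0.0, 1.2, 13)
            land = meanfield.landscape(mu_grid, sig_grid, mf)
            meanfield.landscape_to_frame(land).to_csv(
                out / "meanfield_landscape.csv", index=False)
            (out / "meanfield_meta.json").write_text(json.dumps({
                "w_max": mf.w_max, "Q": mf.Q, "N_E": mf.N_E,
                "boundary_mu": list(map(float, land["boundary_mu"])),
            }, indent=2, default=float))
            manifest.outputs[st] = ["meanfield_landscape.csv",
                                    "meanfield_meta.json"]
        manifest.completed.append(st)
        manifest.wall_time_s[st] = round(time.monotonic() - t0, 3)
        manifest.write(out / "manifest.json")
        log.info("stage %s done in %.1f s", st, manifest.wall_time_s[st])
    return manifest
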