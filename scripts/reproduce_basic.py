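"""Full basic-network reproduction (not a desk-scale check).

Trains the default 1000-neuron network (Q = 10 overlapping clusters,
one random 500 ms stimulus every 2 s for 10 simulated minutes), then
records 10 minutes of stimulus-free ongoing activity with plasticity
still on, and reports:

* the post-training weight-class trajectory (w1 decaying, w0 rising),
* metastable state segments of the ongoing epoch with duration mean,
  sd and the sd/mean exponentiality diagnostic.

Expect tens of minutes of wall time on one CPU.  Run from the
repository root:

    python scripts/reproduce_basic.py --seed 1 --out scratch/basic
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

import numpy as np

from mpnet import (ExperimentConfig, NetworkConfig, assign_clusters,
                   build_connectivity, detect_states, duration_stats,
                   make_training_schedule, run_session)
from mpnet.analysis import overlaps_from_spikes, segments_to_frame
from mpnet.io import write_spike_table, write_weight_snapshot
from mpnet.protocols import StimulusSchedule

ONGOING_MS = 600_000.0  # 10 minutes of post-training ongoing activity


def basic_protocol(seed: int):
    """Basic-network configuration and its training schedule."""
    net = NetworkConfig(seed=seed)
    cfg = ExperimentConfig(network=net, seed=seed)
    cm = assign_clusters(net.N_E, net.Q, net.f, net.seed)
    schedule = make_training_schedule(
        cm, cfg.training_session_ms, period_ms=cfg.train_period_ms,
        stim_ms=cfg.train_stim_ms, amplitude=net.h_st, seed=seed)
    return cfg, schedule


def main(seed: int, out_dir: str) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg, schedule = basic_protocol(seed)
    net = cfg.network
    cm = assign_clusters(net.N_E, net.Q, net.f, net.seed)
    weights = build_connectivity(net)

    t0 = time.monotonic()
    print(f"training: {cfg.training_session_ms/60000:.0f} simulated minutes")
    trained, rec_train = run_session(weights, schedule, cfg, cluster_map=cm)
    print(f"  done in {time.monotonic()-t0:.0f} s; "
          f"w1={rec_train.w1[-1]:.3f} w0={rec_train.w0[-1]:.4f} mV")
    write_weight_snapshot(out / "trained_weights.npz", trained, seed=seed)

    t0 = time.monotonic()
    print(f"ongoing: {ONGOING_MS/60000:.0f} simulated minutes")
    final, rec_on = run_session(
        trained, StimulusSchedule([], ONGOING_MS), cfg, cluster_map=cm,
        initial_state=rec_train.final_state,
        initial_plasticity=rec_train.final_plasticity)
    print(f"  done in {time.monotonic()-t0:.0f} s")
    write_spike_table(out / "ongoing_spikes.txt", rec_on.spike_times,
                      rec_on.spike_ids, N=net.N, N_E=net.N_E, dt=cfg.dt,
                      seed=seed)

    ov = overlaps_from_spikes(rec_on.spike_times, rec_on.spike_ids, cm,
                              t_start=0.0, t_end=ONGOING_MS)
    segs = detect_states(ov)
    segments_to_frame(segs).to_csv(out / "ongoing_states.csv", index=False)
    stats = duration_stats(segs)
    np.savetxt(out / "ongoing_weight_classes.csv",
               np.column_stack([rec_on.class_times, rec_on.w0, rec_on.w1]),
               header="t_ms w0 w1", comments="# ")

    report = {
        "seed": seed,
        "w1_post_training_mV": float(rec_train.w1[-1]),
        "w0_post_training_mV": float(rec_train.w0[-1]),
        "w1_after_ongoing_mV": float(rec_on.w1[-1]),
        "w0_after_ongoing_mV": float(rec_on.w0[-1]),
        "n_state_segments": stats["n"],
        "state_duration_mean_ms": stats["mean_ms"],
        "state_duration_sd_ms": stats["sd_ms"],
        "sd_over_mean": (None if stats["mean_ms"] is None
                         else stats["sd_ms"] / stats["mean_ms"]),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))
    return report


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="scratch/basic")
    args = ap.parse_args()
    main(args.seed, args.out)
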