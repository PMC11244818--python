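"""Stimulation schedules and session execution.

Training presents one randomly chosen stimulus per fixed period; the
perturbation protocols deliver brief stimuli at Poisson times in one of
three scenarios:

``random``
    every event targets a freshly drawn Bernoulli(f) subset of E
    neurons (a purely noisy environment, each stimulus used once);
``mixed``
    each event is, with probability 1/2, a fresh random set and
    otherwise one of the Q stimuli of a second, reoccurring set;
``novel``
    all events are drawn uniformly from the second set (retraining).

:func:`run_session` executes a schedule with the compiled kernel,
optionally applying plasticity, and records spikes, periodic weight
snapshots and w0/w1 class averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .config import ExperimentConfig
from .construction import ClusterMap, WeightMatrix, substream
from .core import NetworkState
from .plasticity import PlasticityState

__all__ = [
    "RANDOM_STIMULUS",
    "StimulusEvent",
    "StimulusSchedule",
    "SessionRecording",
    "make_training_schedule",
    "make_perturbation_schedule",
    "run_session",
]

RANDOM_STIMULUS = -1  # stimulus_id of a one-off random target set

_SCENARIOS = ("random", "mixed", "novel")


@dataclass
class StimulusEvent:
    onset: float            # ms
    duration: float         # ms
    stimulus_id: int        # index into the cluster map, or RANDOM_STIMULUS
    targets: np.ndarray     # excitatory neuron indices
    amplitude: float        # stimulus current h_st (mV/ms)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be > 0")
        self.targets = np.asarray(self.targets, dtype=np.int64)


@dataclass
class StimulusSchedule:
    events: list[StimulusEvent]
    session_ms: float
    scenario: str = "none"  # training | random | mixed | novel | none

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)

    def __len__(self) -> int:
        return len(self.events)


def make_training_schedule(
    cluster_map: ClusterMap,
    session_ms: float,
    period_ms: float = 2000.0,
    stim_ms: float = 500.0,
    amplitude: float = 0.5,
    seed: int = 0,
    random_intervals: bool = False,
) -> StimulusSchedule:
    """Training: one uniformly chosen stimulus per period.

    With ``random_intervals`` the presentation onsets form a Poisson
    process with mean interval ``period_ms`` instead of a fixed period;
    the mean presentation count is unchanged.
    """
    if stim_ms >= period_ms:
        raise ValueError("stimulus duration must be shorter than the period")
    rng = substream(seed, "schedule")
    Q = cluster_map.Q
    events = []
    if random_intervals:
        t = rng.exponential(period_ms)
        while t + stim_ms <= session_ms:
            q = int(rng.integers(Q))
            events.append(StimulusEvent(t, stim_ms, q,
                                        cluster_map.targets(q), amplitude))
            t += rng.exponential(period_ms)
    else:
        n = int(session_ms // period_ms)
        for k in range(n):
            q = int(rng.integers(Q))
            events.append(StimulusEvent(k * period_ms, stim_ms, q,
                                        cluster_map.targets(q), amplitude))
    return StimulusSchedule(events, session_ms, scenario="training")


def make_perturbation_schedule(
    scenario: str,
    session_ms: float,
    mean_interval_ms: float = 10_000.0,
    stim_ms: float = 200.0,
    set2: ClusterMap | None = None,
    N_E: int | None = None,
    f: float = 0.1,
    amplitude: float = 0.5,
    seed: int = 0,
) -> StimulusSchedule:
    """Poisson-timed perturbing stimuli in one of the three scenarios.

    ``set2`` (the second, reoccurring stimulus set) is required for the
    ``mixed`` and ``novel`` scenarios; in scenario ``mixed`` its events
    are interleaved 50/50 with one-off random target sets.  Random sets
    are fresh Bernoulli(f) draws over the ``N_E`` excitatory neurons.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {_SCENARIOS}")
    if scenario in ("mixed", "novel") and set2 is None:
        raise ValueError(f"scenario {scenario!r} requires the reoccurring set2")
    if N_E is None:
        if set2 is None:
            raise ValueError("N_E is required when no set2 is given")
        N_E = set2.N_E
    rng = substream(seed, "perturbation")
    events = []
    t = rng.exponential(mean_interval_ms)
    while t < session_ms:
        if scenario == "novel" or (scenario == "mixed" and rng.random() < 0.5):
            q = int(rng.integers(set2.Q))
            events.append(StimulusEvent(t, stim_ms, q,
                                        set2.targets(q), amplitude))
        else:
            targets = np.flatnonzero(rng.random(N_E) < f)
            events.append(StimulusEvent(t, stim_ms, RANDOM_STIMULUS,
                                        targets, amplitude))
        t += rng.exponential(mean_interval_ms)
    return StimulusSchedule(events, session_ms, scenario=scenario)


@dataclass
class SessionRecording:
    """Spikes, periodic snapshots and weight-class series of one session."""

    dt: float
    N: int
    N_E: int
    seed: int
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    class_times: np.ndarray | None = None   # ms
    w0: np.ndarray | None = None            # mean weight, no shared stimulus
    w1: np.ndarray | None = None            # mean weight, >= 1 shared stimulus
    snapshot_times: list[float] = field(default_factory=list)
    weight_snapshots: list[np.ndarray] = field(default_factory=list)
    plasticity_snapshots: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = \
        field(default_factory=list)
    final_state: NetworkState | None = None
    final_plasticity: PlasticityState | None = None


def _event_arrays(schedule: StimulusSchedule, dt: float, N_E: int):
    """Convert a schedule into the flat step-indexed arrays of the kernel."""
    n = len(schedule.events)
    on = np.empty(n, dtype=np.int64)
    off = np.empty(n, dtype=np.int64)
    amp = np.empty(n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    idx_parts = []
    for e, ev in enumerate(schedule.events):
        if ev.targets.size and ev.targets.max() >= N_E:
            raise ValueError("stimulus targets must be excitatory neurons")
        on[e] = int(round(ev.onset / dt))
        off[e] = on[e] + max(1, int(round(ev.duration / dt)))
        amp[e] = ev.amplitude
        indptr[e + 1] = indptr[e] + ev.targets.size
        idx_parts.append(ev.targets.astype(np.int64))
    idx = np.concatenate(idx_parts) if idx_parts else np.empty(0, dtype=np.int64)
    off_order = np.argsort(off, kind="stable").astype(np.int64)
    return on, off, indptr, idx, amp, off_order


def run_session(
    weights: WeightMatrix,
    schedule: StimulusSchedule,
    cfg: ExperimentConfig,
    *,
    plasticity_on: bool = True,
    cluster_map: ClusterMap | None = None,
    initial_state: NetworkState | None = None,
    initial_plasticity: PlasticityState | None = None,
    record_plasticity: bool = False,
    chunk_ms: float = 1000.0,
) -> tuple[WeightMatrix, SessionRecording]:
    """Simulate one session of the network under a stimulation schedule.

    The input weight matrix is left untouched; the returned matrix holds
    the final efficacies.  With ``plasticity_on=False`` the returned
    matrix equals the input bit for bit.  Given the same configuration,
    seeds and initial conditions the recording is fully deterministic.

    Weight-class averages (w0/w1) are recorded every
    ``cfg.class_interval_ms`` when a ``cluster_map`` is supplied; full
    weight snapshots every ``cfg.snapshot_interval_ms``.
    """
    from .analysis import mean_weights_by_class  # local import, no cycle

    net, neu, pl = cfg.network, cfg.neuron, cfg.plasticity
    dt = cfg.dt
    N, N_E = weights.N, weights.N_E
    if net.N != N or net.N_E != N_E:
        raise ValueError("network config does not match the weight matrix")

    work = weights.copy()
    csr = work.csr
    data = csr.data
    indptr64 = csr.indptr.astype(np.int64)
    indices64 = csr.indices.astype(np.int64)

    if initial_state is None:
        state = NetworkState.initial(N, N_E, neu,
                                     substream(cfg.seed, "initial_state"))
    else:
        state = initial_state.copy()
    ps = (initial_plasticity.copy() if initial_plasticity is not None
          else PlasticityState.zeros(N_E))

    from .plasticity import exp_voltage_term

    expv = np.asarray(exp_voltage_term(state.V, neu), dtype=float)
    h_ext = np.where(np.arange(N) < N_E, net.h_ext_E, net.h_ext_I)
    h_st = np.zeros(N)
    on, off, ev_indptr, ev_idx, ev_amp, off_order = _event_arrays(
        schedule, dt, N_E)
    ptrs = np.zeros(2, dtype=np.int64)

    n_steps_total = int(round(schedule.session_ms / dt))
    chunk_steps = max(1, int(round(chunk_ms / dt)))
    cap = int(2 * N * chunk_ms) + 1024  # > 1 spike/ms/neuron is unphysical
    spike_t = np.empty(cap)
    spike_i = np.empty(cap, dtype=np.int32)

    rec = SessionRecording(dt=dt, N=N, N_E=N_E, seed=cfg.seed)
    sp_t_parts, sp_i_parts = [], []
    class_times, w0s, w1s = [], [], []
    class_every = max(1, int(round(cfg.class_interval_ms / chunk_ms)))
    snap_every = max(1, int(round(cfg.snapshot_interval_ms / chunk_ms)))

    def record_class(t_ms: float) -> None:
        if cluster_map is not None:
            w0, w1, _, _ = mean_weights_by_class(work, cluster_map)
            class_times.append(t_ms)
            w0s.append(w0)
            w1s.append(w1)

    def record_snapshot(t_ms: float) -> None:
        rec.snapshot_times.append(t_ms)
        rec.weight_snapshots.append(data.copy())
        if record_plasticity:
            rec.plasticity_snapshots.append(
                (ps.v_tilde.copy(), ps.s_tilde.copy(), ps.theta.copy()))

    record_class(0.0)
    record_snapshot(0.0)

    spiked = state.spiked.astype(np.uint8)
    step = 0
    n_chunk = 0
    while step < n_steps_total:
        n = min(chunk_steps, n_steps_total - step)
        status, n_sp, bad = _kernel.run_chunk(
            state.V, expv, state.h_E_syn, state.h_I_syn, spiked,
            ps.v_tilde, ps.s_tilde, ps.theta, h_st,
            indptr64, indices64, data, N_E,
            neu.V_L, neu.V_T, neu.Delta_T, neu.V_peak, neu.V_r,
            neu.tau_m_E, neu.tau_m_I, neu.tau_syn_E, neu.tau_syn_I,
            h_ext,
            plasticity_on, pl.A_LTP, pl.A_LTD, pl.beta,
            pl.tau_v, pl.tau_s, pl.tau_theta, pl.theta_a, pl.g, pl.gamma,
            on, off, ev_indptr, ev_idx, ev_amp, off_order, ptrs,
            dt, step, n,
            spike_t, spike_i,
        )
        if status == _kernel.ERR_NONFINITE:
            raise FloatingPointError(
                f"non-finite membrane potential for neuron {bad} near "
                f"t={(step + n) * dt:.1f} ms (dt={dt})"
            )
        if status == _kernel.ERR_SPIKE_OVERFLOW:
            raise RuntimeError(
                "runaway activity: spike buffer overflow "
                f"(> {cap} spikes in a {chunk_ms} ms chunk)"
            )
        sp_t_parts.append(spike_t[:n_sp].copy())
        sp_i_parts.append(spike_i[:n_sp].copy())
        step += n
        n_chunk += 1
        t_ms = step * dt
        if n_chunk % class_every == 0:
            record_class(t_ms)
        if n_chunk % snap_every == 0:
            record_snapshot(t_ms)

    if rec.snapshot_times[-1] != n_steps_total * dt:
        record_snapshot(n_steps_total * dt)
    if cluster_map is not None and (not class_times
                                    or class_times[-1] != n_steps_total * dt):
        record_class(n_steps_total * dt)

    bad_w = ~np.isfinite(data)
    if bad_w.any():
        raise FloatingPointError(
            f"{int(bad_w.sum())} non-finite synaptic weights at session end"
        )

    rec.spike_times = (np.concatenate(sp_t_parts)
                       if sp_t_parts else np.empty(0))
    rec.spike_ids = (np.concatenate(sp_i_parts)
                     if sp_i_parts else np.empty(0, dtype=np.int32))
    if cluster_map is not None:
        rec.class_times = np.asarray(class_times)
        rec.w0 = np.asarray(w0s)
        rec.w1 = np.asarray(w1s)
    state.spiked = spiked.astype(bool)
    state.t = n_steps_total * dt
    rec.final_state = state
    rec.final_plasticity = ps
    return work, rec
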