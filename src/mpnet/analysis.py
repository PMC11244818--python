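"""Overlaps, metastable-state segmentation and weight-class dynamics.

The central observable is the overlap

    m_q(t) = sum_i eta_{q,i} nu_i(t) / sum_i nu_i(t)

between the instantaneous excitatory activity and the target set of
stimulus q: it approaches 1 when only neurons of cluster q fire and 0
when they are silent.  A memory state for stimulus q is *active*
whenever m_q(t) > 0.5 (strict); maximal runs above threshold are the
metastable state segments whose duration statistics are approximately
exponential in the trained network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .construction import ClusterMap, WeightMatrix

__all__ = [
    "RateSeries",
    "OverlapSeries",
    "StateSegment",
    "estimate_rates",
    "overlaps",
    "overlaps_from_spikes",
    "detect_states",
    "segments_to_frame",
    "duration_stats",
    "mean_weights_by_class",
    "weight_change_rate",
]


@dataclass
class RateSeries:
    """Per-neuron instantaneous firing-rate estimates on a regular grid.

    ``rates[k, i]`` is the causal boxcar estimate for neuron i at time
    ``times[k]``: the spike count over (t - window_ms, t] divided by the
    window, in spikes/s.
    """

    times: np.ndarray        # ms
    rates: np.ndarray        # (n_times, n_neurons), spikes/s
    window_ms: float


@dataclass
class OverlapSeries:
    times: np.ndarray        # ms
    m: np.ndarray            # (n_times, Q), each in [0, 1]


@dataclass
class StateSegment:
    cluster: int
    onset: float             # ms
    offset: float            # ms
    complete: bool           # False if truncated at a recording boundary

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _count_grid(spike_times, spike_ids, n_neurons, window_ms, grid_ms,
                t_start, t_end):
    """Boxcar spike counts per (grid time, neuron) via bin cumsums."""
    if window_ms <= 0 or grid_ms <= 0:
        raise ValueError("window_ms and grid_ms must be > 0")
    if window_ms % grid_ms:
        raise ValueError("window_ms must be a multiple of grid_ms")
    n_bins = int(np.ceil((t_end - t_start) / grid_ms))
    w_bins = int(round(window_ms / grid_ms))
    keep = (spike_times > t_start) & (spike_times <= t_end)
    b = np.minimum(
        ((spike_times[keep] - t_start) / grid_ms - 1e-9).astype(np.int64),
        n_bins - 1,
    )
    ids = np.asarray(spike_ids)[keep]
    counts = np.zeros((n_bins, n_neurons))
    np.add.at(counts, (b, ids), 1.0)
    cum = np.cumsum(counts, axis=0)
    boxcar = cum - np.vstack([np.zeros((w_bins, n_neurons)),
                              cum[:-w_bins]])[:n_bins]
    times = t_start + grid_ms * (1 + np.arange(n_bins))
    return times, boxcar


def estimate_rates(spike_times, spike_ids, n_neurons: int,
                   window_ms: float = 50.0, grid_ms: float = 10.0,
                   t_start: float = 0.0,
                   t_end: float | None = None) -> RateSeries:
    """Causal boxcar firing-rate estimate on a regular grid (spikes/s)."""
    spike_times = np.asarray(spike_times, dtype=float)
    if t_end is None:
        t_end = float(spike_times.max()) if spike_times.size else t_start + grid_ms
    times, counts = _count_grid(spike_times, spike_ids, n_neurons,
                                window_ms, grid_ms, t_start, t_end)
    return RateSeries(times, counts * (1000.0 / window_ms), window_ms)


def overlaps(rates: RateSeries, cluster_map: ClusterMap) -> OverlapSeries:
    """Overlap m_q(t) of the excitatory activity with each stimulus.

    Only the first N_E columns of the rate series (the excitatory
    neurons) enter.  When the total rate is zero, m_q is defined as 0.
    """
    eta = cluster_map.eta.astype(float)
    nu = rates.rates[:, :cluster_map.N_E]
    num = nu @ eta.T                      # (n_times, Q)
    den = nu.sum(axis=1, keepdims=True)
    m = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return OverlapSeries(rates.times, m)


def overlaps_from_spikes(spike_times, spike_ids, cluster_map: ClusterMap,
                         window_ms: float = 50.0, grid_ms: float = 10.0,
                         t_start: float = 0.0,
                         t_end: float | None = None) -> OverlapSeries:
    """Memory-light overlap computation straight from the spike table.

    Equivalent to ``overlaps(estimate_rates(...), cluster_map)`` because
    the boxcar window cancels between numerator and denominator, but it
    never materializes the per-neuron rate matrix.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    spike_ids = np.asarray(spike_ids)
    N_E = cluster_map.N_E
    keep = spike_ids < N_E
    ts, ids = spike_times[keep], spike_ids[keep]
    if t_end is None:
        t_end = float(spike_times.max()) if spike_times.size else t_start + grid_ms
    if window_ms <= 0 or grid_ms <= 0:
        raise ValueError("window_ms and grid_ms must be > 0")
    if window_ms % grid_ms:
        raise ValueError("window_ms must be a multiple of grid_ms")
    n_bins = int(np.ceil((t_end - t_start) / grid_ms))
    w_bins = int(round(window_ms / grid_ms))
    sel = (ts > t_start) & (ts <= t_end)
    b = np.minimum(((ts[sel] - t_start) / grid_ms - 1e-9).astype(np.int64),
                   n_bins - 1)
    ids = ids[sel]
    Q = cluster_map.Q
    per_cluster = np.zeros((n_bins, Q))
    eta = cluster_map.eta
    for q in range(Q):
        in_q = eta[q, ids].astype(bool)
        np.add.at(per_cluster[:, q], b[in_q], 1.0)
    total = np.zeros(n_bins)
    np.add.at(total, b, 1.0)

    def boxcar(x):
        cum = np.cumsum(x, axis=0)
        pad = np.zeros((w_bins,) + x.shape[1:])
        return cum - np.concatenate([pad, cum[:-w_bins]])[:n_bins]

    num = boxcar(per_cluster)
    den = boxcar(total)[:, None]
    m = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    times = t_start + grid_ms * (1 + np.arange(n_bins))
    return OverlapSeries(times, m)


def detect_states(ov: OverlapSeries, threshold: float = 0.5
                  ) -> list[StateSegment]:
    """Maximal runs of samples with m_q strictly above threshold.

    Each sample at grid time t represents the interval (t - grid, t];
    a run of k samples therefore spans k grid steps.  Runs touching the
    first or last sample are flagged incomplete.
    """
    times = ov.times
    if times.size < 2:
        return []
    grid = float(times[1] - times[0])
    segments: list[StateSegment] = []
    for q in range(ov.m.shape[1]):
        above = ov.m[:, q] > threshold
        if not above.any():
            continue
        d = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if above[0]:
            starts = np.concatenate([[0], starts])
        if above[-1]:
            ends = np.concatenate([ends, [above.size]])
        for s, e in zip(starts, ends):
            complete = s > 0 and e < above.size
            segments.append(StateSegment(q, times[s] - grid, times[e - 1],
                                         complete))
    segments.sort(key=lambda seg: (seg.onset, seg.cluster))
    return segments


def segments_to_frame(segments: list[StateSegment]) -> pd.DataFrame:
    """State-segment table (cluster_id, onset_ms, offset_ms, duration_ms,
    complete_flag), ready to be written as CSV."""
    return pd.DataFrame(
        {
            "cluster_id": [s.cluster for s in segments],
            "onset_ms": [s.onset for s in segments],
            "offset_ms": [s.offset for s in segments],
            "duration_ms": [s.duration for s in segments],
            "complete_flag": [s.complete for s in segments],
        }
    )


def duration_stats(segments: list[StateSegment], n_bins: int = 20) -> dict:
    """Summary of complete-segment durations.

    The ``exponentiality`` diagnostic is |sd/mean - 1|: for exponential
    dwell times sd approximately equals the mean.  Boundary-truncated
    segments are excluded because they bias the mean.
    """
    durations = np.array([s.duration for s in segments if s.complete])
    if durations.size == 0:
        return {"n": 0, "mean_ms": None, "sd_ms": None,
                "exponentiality": None, "hist": None, "bin_edges": None}
    mean = float(durations.mean())
    if durations.size < 2:
        return {"n": 1, "mean_ms": mean, "sd_ms": None,
                "exponentiality": None, "hist": None, "bin_edges": None}
    sd = float(durations.std(ddof=1))
    hist, edges = np.histogram(durations, bins=n_bins, density=True)
    return {
        "n": int(durations.size),
        "mean_ms": mean,
        "sd_ms": sd,
        "exponentiality": abs(sd / mean - 1.0),
        "hist": hist,
        "bin_edges": edges,
    }


def _shared_stimulus(cluster_map: ClusterMap) -> np.ndarray:
    """Boolean (N_E, N_E): pair shares at least one stimulus."""
    eta = cluster_map.eta.astype(np.int32)
    return (eta.T @ eta) > 0


def mean_weights_by_class(weights: WeightMatrix, cluster_map: ClusterMap
                          ) -> tuple[float, float, int, int]:
    """Mean plastic efficacy by shared-stimulus class.

    A plastic synapse (i <- j) is class 1 when pre- and postsynaptic
    neurons share at least one stimulus, class 0 otherwise.  Returns
    (w0, w1, N0, N1); an empty class has mean NaN.
    """
    N_E = weights.N_E
    if cluster_map.N_E != N_E:
        raise ValueError("cluster map does not match the weight matrix")
    csr = weights.csr
    indptr, indices, data = csr.indptr, csr.indices, csr.data
    shared = _shared_stimulus(cluster_map)
    s0 = s1 = 0.0
    n0 = n1 = 0
    for j in range(N_E):                     # presynaptic E rows
        lo, hi = indptr[j], indptr[j + 1]
        cols = indices[lo:hi]
        sel = cols < N_E
        cols = cols[sel]
        vals = data[lo:hi][sel]
        cls1 = shared[j, cols]
        s1 += vals[cls1].sum()
        n1 += int(cls1.sum())
        s0 += vals[~cls1].sum()
        n0 += int((~cls1).sum())
    w0 = s0 / n0 if n0 else float("nan")
    w1 = s1 / n1 if n1 else float("nan")
    return w0, w1, n0, n1


def weight_change_rate(times_ms: np.ndarray, series_by_N: dict[int, np.ndarray]
                       ) -> dict:
    """N-scaled synaptic rates of change for cross-size comparison.

    For each network size N, the finite-difference rate dw_C/dt over the
    common snapshot grid is multiplied by N; the drift argument predicts
    these curves to coincide for large N under cluster-size-preserving
    scaling.  Returns per-N curves (on the interval midpoints) and the
    maximum pairwise gap between them.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms.size < 2:
        raise ValueError("need at least 2 snapshot times")
    if np.any(np.diff(times_ms) <= 0):
        raise ValueError("snapshot times must be strictly increasing")
    dt = np.diff(times_ms)
    mid = 0.5 * (times_ms[:-1] + times_ms[1:])
    curves = {}
    for N, w in series_by_N.items():
        w = np.asarray(w, dtype=float)
        if w.size != times_ms.size:
            raise ValueError(f"series for N={N} does not match the time grid")
        curves[N] = N * np.diff(w) / dt
    gap = 0.0
    keys = sorted(curves)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            gap = max(gap, float(np.max(np.abs(curves[keys[a]]
                                               - curves[keys[b]]))))
    return {"times_ms": mid, "scaled_rates": curves, "max_pairwise_gap": gap}
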