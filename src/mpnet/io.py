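"""Round-trippable on-disk formats for spikes, weights and filter states.

Spike tables are plain text (stable across platforms and diffable):
a commented header with the run metadata followed by two columns,
time in ms with 3 decimals and the 0-based neuron index, sorted by time.
Weight and plasticity snapshots use numpy ``.npz`` containers with a
format-version tag; round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .construction import WeightMatrix
from .plasticity import PlasticityState

__all__ = [
    "write_spike_table", "read_spike_table",
    "write_weight_snapshot", "read_weight_snapshot",
    "write_plasticity_state", "read_plasticity_state",
]

SPIKE_FORMAT = 1
WEIGHT_FORMAT = 1


def write_spike_table(path: str | Path, times: np.ndarray, ids: np.ndarray,
                      *, N: int, N_E: int, dt: float, seed: int) -> None:
    """Write a spike table: '# key=value' header, then 'time_ms neuron'."""
    times = np.asarray(times, dtype=float)
    ids = np.asarray(ids, dtype=np.int64)
    order = np.lexsort((ids, times))
    with open(path, "w") as fh:
        fh.write(f"# mpnet spike table v{SPIKE_FORMAT}\n")
        fh.write(f"# N={N} N_E={N_E} dt={dt!r} seed={seed}\n")
        fh.write("# time_ms neuron\n")
        for t, i in zip(times[order], ids[order]):
            fh.write(f"{t:.3f} {i}\n")


def read_spike_table(path: str | Path
                     ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a spike table; returns (times_ms, neuron_ids, metadata)."""
    meta: dict = {}
    times, ids = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, val = token.split("=", 1)
                        try:
                            meta[key] = int(val)
                        except ValueError:
                            meta[key] = float(val)
                continue
            t, i = line.split()
            times.append(float(t))
            ids.append(int(i))
    return np.asarray(times), np.asarray(ids, dtype=np.int64), meta


def write_weight_snapshot(path: str | Path, weights: WeightMatrix, *,
                          t_ms: float = 0.0, seed: int = 0) -> None:
    """Lossless sparse snapshot of the synaptic matrix."""
    csr = weights.csr
    np.savez_compressed(
        path,
        format=np.int64(WEIGHT_FORMAT),
        N=np.int64(weights.N),
        N_E=np.int64(weights.N_E),
        t_ms=np.float64(t_ms),
        seed=np.int64(seed),
        indptr=csr.indptr,
        indices=csr.indices,
        data=csr.data,
    )


def read_weight_snapshot(path: str | Path) -> tuple[WeightMatrix, dict]:
    with np.load(path) as z:
        N = int(z["N"])
        csr = sp.csr_matrix((z["data"], z["indices"], z["indptr"]),
                            shape=(N, N))
        meta = {"t_ms": float(z["t_ms"]), "seed": int(z["seed"]),
                "format": int(z["format"])}
        return WeightMatrix(csr, int(z["N_E"])), meta


def write_plasticity_state(path: str | Path, ps: PlasticityState, *,
                           t_ms: float = 0.0) -> None:
    np.savez_compressed(path, format=np.int64(WEIGHT_FORMAT),
                        t_ms=np.float64(t_ms), v_tilde=ps.v_tilde,
                        s_tilde=ps.s_tilde, theta=ps.theta)


def read_plasticity_state(path: str | Path) -> tuple[PlasticityState, dict]:
    with np.load(path) as z:
        ps = PlasticityState(z["v_tilde"].copy(), z["s_tilde"].copy(),
                             z["theta"].copy())
        return ps, {"t_ms": float(z["t_ms"]), "format": int(z["format"])}
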