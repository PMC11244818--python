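"""Random E/I network construction, stimulus clusters and size scaling.

Neurons are indexed 0..N-1 with the excitatory population first
(indices < N_E) and the inhibitory population last.  Connectivity is
stored in compressed sparse row form over *presynaptic* neurons: row j
lists the outgoing synapses of neuron j, which is the natural layout for
spike delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NetworkConfig",
    "WeightMatrix",
    "ClusterMap",
    "substream",
    "build_connectivity",
    "assign_clusters",
    "scale_network",
]

# Fixed, documented derivation of independent seed substreams from one
# master seed.  Varying one component (e.g. the stimulus schedule) while
# holding the others fixed only requires changing the consumer's stream.
_STREAMS = {
    "connectivity": 1,
    "clusters": 2,
    "initial_state": 3,
    "schedule": 4,
    "perturbation": 5,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from one master seed."""
    try:
        key = _STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class NetworkConfig:
    """Sizes, connection statistics and input currents of the network."""

    N: int = 1000
    N_E: int = 800
    N_I: int = 200
    p_EE: float = 0.2
    p_EI: float = 0.5   # I -> E connection probability
    p_IE: float = 0.5   # E -> I
    p_II: float = 0.5
    w_EE: float = 0.005   # initial E->E efficacy (mV), plastic
    w_EI: float = -0.34   # I -> E efficacy (mV)
    w_IE: float = 0.54    # E -> I efficacy (mV)
    w_II: float = -0.46   # I -> I efficacy (mV)
    h_ext_E: float = 1.50  # constant external current to E (mV/ms)
    h_ext_I: float = 2.19  # constant external current to I (mV/ms)
    h_st: float = 0.5      # stimulus current (mV/ms)
    Q: int = 10            # number of stimuli
    f: float = 0.1         # coding level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_E + self.N_I != self.N:
            raise ValueError(f"N_E + N_I = {self.N_E + self.N_I} != N = {self.N}")
        if min(self.N_E, self.N_I) <= 0:
            raise ValueError("population sizes must be positive")
        for name in ("p_EE", "p_EI", "p_IE", "p_II"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"coding level f = {self.f} outside (0, 1]")
        if self.w_EE < 0 or self.w_IE < 0:
            raise ValueError("efficacies from excitatory neurons must be >= 0")
        if self.w_EI > 0 or self.w_II > 0:
            raise ValueError("efficacies from inhibitory neurons must be <= 0")
        if self.Q < 1:
            raise ValueError("Q must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


class WeightMatrix:
    """Signed, population-typed synaptic efficacies in presynaptic-row CSR.

    ``csr[j, i]`` is the efficacy of the synapse from neuron j onto
    neuron i.  The sparsity pattern is fixed at construction; plasticity
    only rescales existing E->E entries (the ``plastic_mask``), which are
    clamped at zero from below so Dale's law is preserved forever.
    """

    def __init__(self, csr: sp.csr_matrix, N_E: int):
        csr = sp.csr_matrix(csr)
        if csr.shape[0] != csr.shape[1]:
            raise ValueError("weight matrix must be square")
        csr.sort_indices()
        self.csr = csr
        self.N = csr.shape[0]
        self.N_E = int(N_E)
        if not 0 < self.N_E <= self.N:
            raise ValueError("N_E out of range")

    @property
    def N_I(self) -> int:
        return self.N - self.N_E

    @property
    def plastic_mask(self) -> np.ndarray:
        """Boolean mask over csr.data marking existing E->E synapses."""
        n_out = np.diff(self.csr.indptr)
        pre_is_E = np.repeat(np.arange(self.N) < self.N_E, n_out)
        post_is_E = self.csr.indices < self.N_E
        return pre_is_E & post_is_E

    def n_plastic(self) -> int:
        return int(self.plastic_mask.sum())

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.csr.copy(), self.N_E)

    def check_dale(self) -> bool:
        """True iff every E row is nonnegative and every I row nonpositive."""
        n_out = np.diff(self.csr.indptr)
        pre_is_E = np.repeat(np.arange(self.N) < self.N_E, n_out)
        return bool(
            (self.csr.data[pre_is_E] >= 0).all()
            and (self.csr.data[~pre_is_E] <= 0).all()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightMatrix):
            return NotImplemented
        return (
            self.N_E == other.N_E
            and np.array_equal(self.csr.indptr, other.csr.indptr)
            and np.array_equal(self.csr.indices, other.csr.indices)
            and np.array_equal(self.csr.data, other.csr.data)
        )


@dataclass
class ClusterMap:
    """Binary stimulus->neuron membership indicator eta, shape (Q, N_E)."""

    eta: np.ndarray

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta)
        if eta.ndim != 2:
            raise ValueError("eta must be 2-D (Q, N_E)")
        if not np.isin(eta, (0, 1)).all():
            raise ValueError("eta entries must be 0 or 1")
        self.eta = eta.astype(np.uint8)

    @property
    def Q(self) -> int:
        return self.eta.shape[0]

    @property
    def N_E(self) -> int:
        return self.eta.shape[1]

    def targets(self, q: int) -> np.ndarray:
        """Indices of the excitatory neurons in cluster q."""
        return np.flatnonzero(self.eta[q])

    def cluster_sizes(self) -> np.ndarray:
        return self.eta.sum(axis=1).astype(int)

    def membership_counts(self) -> np.ndarray:
        """Number of clusters each excitatory neuron belongs to."""
        return self.eta.sum(axis=0).astype(int)

    def stats(self) -> dict:
        """Summary statistics of the cluster assignment.

        Reports the mean cluster size, the fraction of excitatory
        neurons that respond to no stimulus, and multi-membership
        fractions both over all neurons and over responsive neurons.
        """
        counts = self.membership_counts()
        n = counts.size
        responsive = counts > 0
        multi = counts >= 2
        n_resp = int(responsive.sum())
        n_member = int(counts.sum())
        # membership-weighted multi fraction: the probability that a
        # neuron of a given cluster also belongs to another cluster,
        # with expectation 1 - (1-f)^(Q-1) under Bernoulli membership
        shared = float(counts[multi].sum() / n_member) if n_member else 0.0
        return {
            "shared_membership_fraction": shared,
            "mean_cluster_size": float(self.cluster_sizes().mean()),
            "sd_cluster_size": float(self.cluster_sizes().std(ddof=0)),
            "non_responsive_fraction": float((~responsive).mean()),
            "responsive_fraction": float(responsive.mean()),
            "multi_membership_fraction": float(multi.mean()),
            "multi_given_responsive": float(multi.sum() / n_resp) if n_resp else 0.0,
            "n_neurons": n,
        }


def build_connectivity(cfg: NetworkConfig) -> WeightMatrix:
    """Draw the quenched random connectivity of the network.

    Each ordered pair (j -> i, j != i) is connected independently with
    the probability of its population pair and initialized to the
    constant efficacy of that pair.  Self-connections are excluded.
    """
    rng = substream(cfg.seed, "connectivity")
    N, N_E = cfg.N, cfg.N_E
    post_is_E = np.arange(N) < N_E

    # probability and initial weight per (pre-population, post-population)
    # row; p_EI is the probability of an I->E synapse (post E, pre I).
    p_row_E = np.where(post_is_E, cfg.p_EE, cfg.p_IE)
    w_row_E = np.where(post_is_E, cfg.w_EE, cfg.w_IE)
    p_row_I = np.where(post_is_E, cfg.p_EI, cfg.p_II)
    w_row_I = np.where(post_is_E, cfg.w_EI, cfg.w_II)

    # Chunk over presynaptic rows to bound memory at large N.  The RNG
    # consumes uniforms in row-major order, so the result is independent
    # of the chunk size.
    chunk = 1024
    indptr = np.zeros(N + 1, dtype=np.int64)
    idx_parts, w_parts = [], []
    for j0 in range(0, N, chunk):
        j1 = min(j0 + chunk, N)
        u = rng.random((j1 - j0, N))
        pre_E = np.arange(j0, j1) < N_E
        mask = u < np.where(pre_E[:, None], p_row_E, p_row_I)
        mask[np.arange(j1 - j0), np.arange(j0, j1)] = False  # no self-loops
        rows, cols = np.nonzero(mask)
        idx_parts.append(cols.astype(np.int32))
        w_parts.append(np.where(pre_E[rows], w_row_E[cols], w_row_I[cols]))
        indptr[j0 + 1:j1 + 1] = indptr[j0] + np.cumsum(mask.sum(axis=1))
    csr = sp.csr_matrix(
        (np.concatenate(w_parts), np.concatenate(idx_parts), indptr),
        shape=(N, N),
    )
    return WeightMatrix(csr, N_E)


def assign_clusters(N_E: int, Q: int, f: float, seed: int) -> ClusterMap:
    """Independent Bernoulli(f) stimulus membership for each (q, neuron)."""
    if not 0.0 < f <= 1.0:
        raise ValueError(f"coding level f = {f} outside (0, 1]")
    if Q < 1:
        raise ValueError("Q must be >= 1")
    rng = substream(seed, "clusters")
    eta = (rng.random((Q, N_E)) < f).astype(np.uint8)
    return ClusterMap(eta)


def scale_network(N: int, regime: str) -> tuple[int, int, int, float]:
    """Population sizes and stimulus statistics for a network of N neurons.

    regime "linear": Q grows with N (Q = N/100, f = 1/Q) so the mean
    cluster size f*N_E stays at 80 neurons.  regime "sqrt": Q grows like
    sqrt(N) (Q = round(sqrt(N/10)), f = 1/Q) so clusters grow with N.
    Both coincide with the basic network at N = 1000.

    Returns (N_E, N_I, Q, f).
    """
    if N < 1000:
        raise ValueError("scaling is defined for N >= 1000")
    N_E = int(round(0.8 * N))
    N_I = N - N_E
    if regime == "linear":
        Q = int(round(N / 100))
    elif regime == "sqrt":
        Q = int(round(np.sqrt(N / 10)))
    else:
        raise ValueError(f"unknown scaling regime {regime!r}")
    return N_E, N_I, Q, 1.0 / Q
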