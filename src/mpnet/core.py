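"""Reference time-stepped dynamics of the EIF network.

This module contains a plain-numpy implementation of one network update
step, used for small networks, unit tests and as the executable
definition of the update order.  Production sessions run the compiled
kernel in :mod:`mpnet._kernel`, which implements exactly the same
per-step arithmetic.

Update order within one step of size dt (fixed and relied upon by the
plasticity rule):

1. decay the synaptic filters by exp(-dt/tau_syn) and deliver the spikes
   emitted at the *previous* step as jumps w/tau_syn (one-step delivery
   delay, no explicit axonal delays);
2. advance all membrane potentials by one explicit forward-Euler step,
   with the exponential term evaluated at V clipped to V_peak;
3. detect spikes (V >= V_peak), time-stamp them at the end of the step
   and reset to V_r.

Plasticity, when enabled, is triggered in stage 1: each delivered
presynaptic E spike updates its E->E synapse using the postsynaptic
filter values carried over from the previous step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .construction import WeightMatrix
from .params import NeuronParams
from .plasticity import exp_voltage_term

__all__ = ["NetworkState", "DriveVector", "membrane_step",
           "synaptic_filter_step", "step_network"]


@dataclass
class NetworkState:
    """Membrane potentials and synaptic filter currents at one time step."""

    t: float                 # current time (ms)
    V: np.ndarray            # membrane potential (mV)
    h_E_syn: np.ndarray      # filtered excitatory recurrent input (mV/ms)
    h_I_syn: np.ndarray      # filtered inhibitory recurrent input (mV/ms)
    spiked: np.ndarray       # bool flags of the current step
    N_E: int                 # neurons [0, N_E) are excitatory
    V_pre: np.ndarray | None = None  # pre-reset V of the last update

    @classmethod
    def initial(cls, N: int, N_E: int, neuron: NeuronParams,
                rng: np.random.Generator) -> "NetworkState":
        """Quiescent state with V drawn uniformly from [V_r, V_T)."""
        V = rng.uniform(neuron.V_r, neuron.V_T, size=N)
        return cls(0.0, V, np.zeros(N), np.zeros(N),
                   np.zeros(N, dtype=bool), N_E)

    def copy(self) -> "NetworkState":
        return NetworkState(self.t, self.V.copy(), self.h_E_syn.copy(),
                            self.h_I_syn.copy(), self.spiked.copy(), self.N_E)


@dataclass
class DriveVector:
    """External input currents (mV/ms): stimulus and constant background."""

    h_st: np.ndarray
    h_ext: np.ndarray


def membrane_step(state: NetworkState, params: NeuronParams,
                  drive: DriveVector, dt: float) -> NetworkState:
    """Advance the membrane equation one forward-Euler step.

    Returns a new state with spiking neurons flagged and reset; spike
    times belong to the end of the step (state.t + dt).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    N = state.V.size
    if np.any(state.V >= params.V_peak):
        raise ValueError("V must be < V_peak on entry")
    tau_m = np.where(np.arange(N) < state.N_E, params.tau_m_E, params.tau_m_I)
    dVdt = (-(state.V - params.V_L) + exp_voltage_term(state.V, params)) / tau_m \
        + state.h_E_syn + state.h_I_syn + drive.h_st + drive.h_ext
    V = state.V + dt * dVdt
    bad = ~np.isfinite(V)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"non-finite membrane potential for neuron {i} at "
            f"t={state.t + dt:.3f} ms (dt={dt})"
        )
    spiked = V >= params.V_peak
    V_post = np.where(spiked, params.V_r, V)
    return NetworkState(state.t + dt, V_post, state.h_E_syn.copy(),
                        state.h_I_syn.copy(), spiked, state.N_E, V_pre=V)


def synaptic_filter_step(h: np.ndarray | float, tau_syn: float,
                         arriving_weight_sum: np.ndarray | float,
                         dt: float) -> np.ndarray | float:
    """Exact exponential decay plus delta-jumps of the synaptic filter.

    Each arriving spike of weight w contributes a jump w/tau_syn (the
    integral of its delta through the first-order filter); simultaneous
    spikes add linearly via ``arriving_weight_sum``.
    """
    if tau_syn <= 0:
        raise ValueError("tau_syn must be > 0")
    return h * np.exp(-dt / tau_syn) + np.asarray(arriving_weight_sum) / tau_syn


def step_network(state: NetworkState, weights: WeightMatrix,
                 params: NeuronParams, drive: DriveVector,
                 dt: float) -> tuple[NetworkState, np.ndarray]:
    """One full network step (delivery, membrane update, spike detection).

    Returns the new state and the indices of neurons that spiked during
    this step.  Plasticity is not applied here; the session engine in
    :mod:`mpnet.protocols` interleaves it at spike delivery.
    """
    if state.V.size != weights.N:
        raise ValueError(
            f"state has {state.V.size} neurons, weights {weights.N}"
        )
    N_E = weights.N_E
    pre = np.flatnonzero(state.spiked)
    pre_E = pre[pre < N_E]
    pre_I = pre[pre >= N_E]
    arriving_E = np.zeros(weights.N)
    arriving_I = np.zeros(weights.N)
    if pre_E.size:
        arriving_E = np.asarray(
            weights.csr[pre_E].sum(axis=0)).ravel()
    if pre_I.size:
        arriving_I = np.asarray(
            weights.csr[pre_I].sum(axis=0)).ravel()
    h_E = synaptic_filter_step(state.h_E_syn, params.tau_syn_E, arriving_E, dt)
    h_I = synaptic_filter_step(state.h_I_syn, params.tau_syn_I, arriving_I, dt)
    mid = NetworkState(state.t, state.V, h_E, h_I, state.spiked, state.N_E)
    out = membrane_step(mid, params, drive, dt)
    return out, np.flatnonzero(out.spiked)
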