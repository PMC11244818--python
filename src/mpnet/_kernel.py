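"""Compiled inner loop of the network simulation.

The kernel advances the full network state over a chunk of steps and
implements, in loop form, exactly the per-step arithmetic of
:mod:`mpnet.core` and :mod:`mpnet.plasticity`:

    1. synaptic filters decay by exp(-dt/tau_syn); spikes emitted at the
       previous step are delivered as jumps w/tau_syn.  A delivered E->E
       spike also triggers the plasticity update of its synapse, using
       the postsynaptic filter values carried over from the previous
       step; the spike itself is delivered with the pre-update weight.
    2. forward-Euler membrane update (exponential term clipped at
       V_peak);
    3. spike detection and reset; the pre-reset potential drives the
       v_tilde filter, then s_tilde and theta advance.

All state arrays are updated in place.  The kernel contains no random
numbers, so identical inputs give bit-identical trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: error codes returned by run_chunk
OK = 0
ERR_NONFINITE = 1
ERR_SPIKE_OVERFLOW = 2


@njit(cache=False, fastmath=True)
def run_chunk(
    # mutable state (in place); expv caches the exponential term at the
    # current V so each neuron evaluates one exp per step
    V, expv, hE, hI, spiked, v_t, s_t, th, h_st,
    # connectivity (CSR over presynaptic rows); data mutated by plasticity
    indptr, indices, data, N_E,
    # neuron parameters
    V_L, V_T, Delta_T, V_peak, V_r,
    tau_m_E, tau_m_I, tau_syn_E, tau_syn_I,
    h_ext,
    # plasticity parameters
    plasticity_on, A_LTP, A_LTD, beta, tau_v, tau_s, tau_theta,
    theta_a, g, gamma,
    # stimulus events (global step indices; onset order and a permutation
    # of event ids sorted by offset)
    ev_on_step, ev_off_step, ev_tgt_indptr, ev_tgt_idx, ev_amp, off_order,
    ptrs,  # int64[2]: persistent (onset, offset) event pointers
    # integration
    dt, step0, n_steps,
    # spike output buffers
    spike_t, spike_i,
):
    """Advance ``n_steps`` steps starting at global step ``step0``.

    Returns (status, n_spikes, bad_neuron).  Spike k is stored as
    (spike_t[k], spike_i[k]) with times in ms at the end of its step.
    """
    N = V.size
    dec_E = np.exp(-dt / tau_syn_E)
    dec_I = np.exp(-dt / tau_syn_I)
    dec_s = np.exp(-dt / tau_s)
    inv_tauE = 1.0 / tau_syn_E
    inv_tauI = 1.0 / tau_syn_I
    c_v = dt / tau_v
    c_th = dt * theta_a / tau_theta
    jump_s = 1.0 / tau_s
    n_ev = ev_on_step.size
    cap = spike_t.size
    n_sp = 0

    for s in range(step0, step0 + n_steps):
        # --- stage 1: filter decay and spike delivery -------------------
        for i in range(N):
            hE[i] *= dec_E
            hI[i] *= dec_I
        for j in range(N):
            if spiked[j]:
                j_is_E = j < N_E
                for k in range(indptr[j], indptr[j + 1]):
                    i = indices[k]
                    w = data[k]
                    if j_is_E:
                        hE[i] += w * inv_tauE
                        if plasticity_on and i < N_E:
                            diff = v_t[i] - th[i]
                            if diff > 0.0:
                                w = w + A_LTP * np.exp(-beta * w * w) * diff
                            else:
                                w = w + A_LTD * diff
                            if w < 0.0:
                                w = 0.0
                            data[k] = w
                    else:
                        hI[i] += w * inv_tauI

        # stimulus events switch on/off at their step boundaries
        while ptrs[0] < n_ev and ev_on_step[ptrs[0]] <= s:
            e = ptrs[0]
            for k in range(ev_tgt_indptr[e], ev_tgt_indptr[e + 1]):
                h_st[ev_tgt_idx[k]] += ev_amp[e]
            ptrs[0] += 1
        while ptrs[1] < n_ev and ev_off_step[off_order[ptrs[1]]] <= s:
            e = off_order[ptrs[1]]
            for k in range(ev_tgt_indptr[e], ev_tgt_indptr[e + 1]):
                h_st[ev_tgt_idx[k]] -= ev_amp[e]
            ptrs[1] += 1

        # --- stages 2-3: membrane update, spike detection, filters ------
        t_spike = (s + 1) * dt
        e_reset = Delta_T * np.exp((V_r - V_T) / Delta_T)
        for i in range(N_E):
            Vi = V[i]
            Vn = Vi + dt * ((-(Vi - V_L) + expv[i]) / tau_m_E
                            + hE[i] + hI[i] + h_st[i] + h_ext[i])
            if not np.isfinite(Vn):
                return ERR_NONFINITE, n_sp, i
            sp = Vn >= V_peak
            # v_tilde is driven by the clipped pre-reset potential
            Vd = Vn if Vn < V_peak else V_peak
            e_new = Delta_T * np.exp((Vd - V_T) / Delta_T)
            v_t[i] += c_v * (e_new - v_t[i])
            s_t[i] = s_t[i] * dec_s + (jump_s if sp else 0.0)
            th[i] += c_th * np.tanh(
                g * (-th[i] + v_t[i] + gamma * s_t[i]))
            if sp:
                V[i] = V_r
                expv[i] = e_reset
                spiked[i] = True
                if n_sp < cap:
                    spike_t[n_sp] = t_spike
                    spike_i[n_sp] = i
                else:
                    return ERR_SPIKE_OVERFLOW, n_sp, i
                n_sp += 1
            else:
                V[i] = Vn
                expv[i] = e_new
                spiked[i] = False
        for i in range(N_E, N):
            Vi = V[i]
            Vn = Vi + dt * ((-(Vi - V_L) + expv[i]) / tau_m_I
                            + hE[i] + hI[i] + h_st[i] + h_ext[i])
            if not np.isfinite(Vn):
                return ERR_NONFINITE, n_sp, i
            if Vn >= V_peak:
                V[i] = V_r
                expv[i] = e_reset
                spiked[i] = True
                if n_sp < cap:
                    spike_t[n_sp] = t_spike
                    spike_i[n_sp] = i
                else:
                    return ERR_SPIKE_OVERFLOW, n_sp, i
                n_sp += 1
            else:
                Vc = Vn if Vn < V_peak else V_peak
                expv[i] = Delta_T * np.exp((Vc - V_T) / Delta_T)
                V[i] = Vn
                spiked[i] = False

    return OK, n_sp, -1
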