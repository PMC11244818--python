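"""Local voltage-based plasticity rule for E->E synapses.

The rule is fully local: a weight update is triggered by the arrival of
a presynaptic spike and reads only the synapse's own efficacy and two
postsynaptic quantities — the low-pass filtered exponential voltage term
``v_tilde`` and an adaptive LTP/LTD threshold ``theta``.  The threshold
slides with postsynaptic activity through a saturating (tanh) dynamics,
which plays the stabilizing role of the sliding threshold in BCM-type
rules: a brief postsynaptic activation opens a transient LTP window,
while sustained firing pulls ``theta`` above ``v_tilde`` (via the
filtered spike train ``s_tilde``) and converts LTP into LTD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import NeuronParams, PlasticityParams

__all__ = [
    "PlasticityState",
    "exp_voltage_term",
    "filter_step",
    "threshold_step",
    "t_half",
    "apply_presynaptic_spike",
]


@dataclass
class PlasticityState:
    """Per-excitatory-neuron postsynaptic filter variables.

    v_tilde : low-pass of the exponential voltage term (mV)
    s_tilde : low-pass of the spike train (1/ms)
    theta   : adaptive LTP/LTD threshold (mV)
    """

    v_tilde: np.ndarray
    s_tilde: np.ndarray
    theta: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "PlasticityState":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n))

    def copy(self) -> "PlasticityState":
        return PlasticityState(
            self.v_tilde.copy(), self.s_tilde.copy(), self.theta.copy()
        )


def exp_voltage_term(V, neuron: NeuronParams):
    """Spike-initiation term Delta_T * exp((V - V_T)/Delta_T), clipped.

    V is clipped at V_peak before the exponential so the term stays
    bounded (at Delta_T * e^5 with default parameters) even at spike
    steps where the raw Euler update may overshoot V_peak.
    """
    V = np.minimum(np.asarray(V, dtype=float), neuron.V_peak)
    return neuron.Delta_T * np.exp((V - neuron.V_T) / neuron.Delta_T)


def filter_step(
    ps: PlasticityState,
    V: np.ndarray,
    spiked: np.ndarray,
    params: PlasticityParams,
    neuron: NeuronParams,
    dt: float,
) -> PlasticityState:
    """Advance the postsynaptic filters v_tilde and s_tilde by one step.

    v_tilde relaxes toward the (clipped) exponential voltage term with a
    forward-Euler step of time constant tau_v.  s_tilde decays exactly
    with tau_s and jumps by 1/tau_s at each postsynaptic spike, which is
    the integral of the delta in the filtered spike-train equation.
    V must be the pre-reset membrane potential of the current step, so
    spike steps drive v_tilde with the clipped value.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    drive = exp_voltage_term(V, neuron)
    v_tilde = ps.v_tilde + (dt / params.tau_v) * (drive - ps.v_tilde)
    s_tilde = ps.s_tilde * np.exp(-dt / params.tau_s)
    s_tilde = s_tilde + np.asarray(spiked, dtype=float) / params.tau_s
    theta = threshold_step(ps.theta, v_tilde, s_tilde, params, dt)
    return PlasticityState(v_tilde, s_tilde, theta)


def threshold_step(theta, v_tilde, s_tilde, params: PlasticityParams, dt: float):
    """One explicit Euler step of the adaptive-threshold dynamics.

        tau_theta * dtheta/dt = theta_a * tanh(g * (-theta + v_tilde
                                                    + gamma * s_tilde))

    The fixed point is theta = v_tilde + gamma * s_tilde; the tanh makes
    the approach time adapt to the distance from it (see :func:`t_half`).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    arg = params.g * (-np.asarray(theta, dtype=float) + v_tilde
                      + params.gamma * np.asarray(s_tilde, dtype=float))
    return theta + (dt * params.theta_a / params.tau_theta) * np.tanh(arg)


def t_half(delta, tau_theta: float):
    """Time for theta to reach half of a step change Delta of its target.

    For tau_theta * dtheta/dt = tanh(Delta - theta) with theta(0) = 0 the
    half-way time has the closed form

        T_half = tau_theta * ln( sinh(Delta) / sinh(Delta/2) )

    which tends to tau_theta * ln 2 for Delta << 1 and grows linearly,
    ~ tau_theta * Delta / 2, for Delta > 3.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("delta must be > 0")
    # sinh(d)/sinh(d/2) = 2*cosh(d/2); the cosh form is overflow-safe.
    out = tau_theta * (np.log(2.0) + np.log(np.cosh(delta / 2.0)))
    return out if out.ndim else float(out)


def apply_presynaptic_spike(w, v_tilde_post, theta_post, params: PlasticityParams):
    """Weight(s) after the arrival of one presynaptic spike.

        dw = A_LTP * exp(-beta w^2) * [v_tilde - theta]_+
             - A_LTD * [theta - v_tilde]_+

    Exactly one of the two terms is nonzero.  The result is clamped at
    zero from below so plastic weights respect Dale's law.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("E->E weights must be nonnegative")
    diff = np.asarray(v_tilde_post, dtype=float) - np.asarray(theta_post, dtype=float)
    ltp = params.A_LTP * np.exp(-params.beta * w**2) * np.maximum(diff, 0.0)
    ltd = params.A_LTD * np.maximum(-diff, 0.0)
    out = np.maximum(w + ltp - ltd, 0.0)
    return out if out.ndim else float(out)
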