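"""Model parameter containers with the standard defaults of the basic network.

Units follow the conventions used throughout the package: membrane
potentials in mV, times and time constants in ms, input currents in
mV/ms (they enter the membrane equation already divided by the membrane
time constant), synaptic efficacies in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class NeuronParams:
    """Single-neuron parameters of the exponential integrate-and-fire model.

    The membrane equation is

        dV/dt = -(V - V_L)/tau_m + (Delta_T/tau_m) * exp((V - V_T)/Delta_T)
                + h_E_syn + h_I_syn + h_st + h_ext

    A spike is emitted when V >= V_peak, after which V is reset to V_r.
    """

    V_L: float = 0.0        # leak potential (mV)
    V_T: float = 20.0       # soft spiking threshold (mV)
    Delta_T: float = 1.0    # spike-initiation sharpness (mV)
    V_peak: float = 25.0    # spike cut-off (mV)
    V_r: float = 0.0        # reset potential (mV)
    tau_m_E: float = 15.0   # excitatory membrane time constant (ms)
    tau_m_I: float = 10.0   # inhibitory membrane time constant (ms)
    tau_syn_E: float = 3.0  # excitatory synaptic time constant (ms)
    tau_syn_I: float = 2.0  # inhibitory synaptic time constant (ms)

    def __post_init__(self) -> None:
        if not (self.V_r <= self.V_L < self.V_T < self.V_peak):
            raise ValueError(
                "require V_r <= V_L < V_T < V_peak, got "
                f"{self.V_r}, {self.V_L}, {self.V_T}, {self.V_peak}"
            )
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be > 0")
        for name in ("tau_m_E", "tau_m_I", "tau_syn_E", "tau_syn_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlasticityParams:
    """Parameters of the voltage-based plasticity rule for E->E synapses.

    A presynaptic spike arriving at synapse (i <- j) changes the weight by

        dw = A_LTP * exp(-beta * w**2) * [v_tilde_i - theta_i]_+
             - A_LTD * [theta_i - v_tilde_i]_+

    where v_tilde_i is the low-pass filtered exponential voltage term of
    the postsynaptic neuron and theta_i an adaptive threshold obeying

        tau_theta * dtheta/dt = theta_a * tanh(g * (-theta + v_tilde
                                                    + gamma * s_tilde)).

    s_tilde is the low-pass filtered postsynaptic spike train (units 1/ms),
    so gamma * s_tilde is in mV.  Weights are clamped at zero from below.
    """

    A_LTP: float = 0.005     # LTP strength (mV per unit of [v_tilde-theta]_+)
    A_LTD: float = 0.015     # LTD strength
    beta: float = 0.1        # LTP attenuation factor (mV^-2)
    tau_v: float = 50.0      # filter constant of v_tilde (ms)
    tau_s: float = 1000.0    # filter constant of s_tilde (ms)
    tau_theta: float = 500.0  # threshold time constant (ms)
    theta_a: float = 1.0     # threshold amplitude (mV)
    g: float = 5.0           # threshold gain (mV^-1)
    gamma: float = 50.0      # spike-train contribution (mV*ms)

    def __post_init__(self) -> None:
        for name in ("tau_v", "tau_s", "tau_theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("A_LTP", "A_LTD", "beta", "g", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)
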