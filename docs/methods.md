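# Methods

## Model summary

The network holds N neurons, 80% excitatory (E) and 20% inhibitory (I),
as exponential integrate-and-fire (EIF) units.  The membrane equation
combines leak, the spike-initiation exponential Δ_T·exp((V−V_T)/Δ_T),
two first-order-filtered recurrent currents (one per presynaptic
population), an optional stimulus current and a constant background
current.  Connectivity is quenched: each ordered pair is connected
independently (p_EE = 0.2, all other pairs 0.5) with a constant initial
efficacy per population pair (w_EE = 0.005, w_EI = −0.34, w_IE = 0.54,
w_II = −0.46 mV).  Self-connections are excluded — the rule would
otherwise self-potentiate a neuron through its own spikes.

Only existing E→E synapses are plastic.  A presynaptic spike changes
the weight by A_LTP·e^{−βw²}[ṽ−θ]₊ − A_LTD·[θ−ṽ]₊ evaluated at the
postsynaptic neuron, where ṽ low-passes the exponential voltage term
(τ_v = 50 ms) and the threshold θ follows τ_θ θ̇ = θ_a tanh(g(−θ + ṽ +
γ s̃)) with the filtered spike train s̃ (τ_s = 1 s).  The tanh makes
the threshold's approach time adapt to the distance from its target:
for a step Δ of the target the half-way time is
T_half = τ_θ ln(sinh Δ / sinh(Δ/2)) (τ_θ ln 2 for small Δ, ~τ_θ Δ/2
beyond Δ ≈ 3).  A single postsynaptic spike therefore opens a brief
LTP window followed by a longer shallow LTD window; sustained firing
raises γs̃ and converts LTP to LTD, which is what terminates prolonged
cluster activations.  Weights are clamped at zero, preserving Dale's
law indefinitely; no upper bound, normalization or inhibitory
plasticity is used.

With the default constants the LTD lobe of the single-spike kernel
integrates to substantially more than the LTP lobe (A_LTD = 3·A_LTP and
θ relaxes more slowly than ṽ decays).  "An occasional spike produces no
meaningful change" is therefore a statement about absolute magnitude:
one isolated spike sampled by a 1 Hz presynaptic train moves a weight
by under 10⁻³ mV, three orders below trained efficacies.

## Integration scheme and update order

Forward Euler with dt = 0.05 ms (configurable).  Each step:

1. synaptic filters decay by exp(−dt/τ_syn); spikes emitted at the
   previous step are delivered as jumps w/τ_syn (one-step delivery
   delay, no explicit axonal delays).  A delivered E→E spike also
   triggers the plasticity update of its synapse using the filter
   values carried over from the previous step; the spike itself is
   delivered with the pre-update weight.
2. membrane update; the exponential term is evaluated with V clipped at
   V_peak, which bounds it at Δ_T e⁵ and keeps the plasticity drive
   finite at spike steps.
3. spikes (V ≥ V_peak) are stamped at the end of the step and reset to
   V_r; the clipped pre-reset potential drives ṽ, then s̃ and θ advance
   (ṽ and θ by Euler, s̃ and the synaptic filters by exact decay).

Initial voltages are drawn uniformly from [V_r, V_T) to desynchronize
startup; filter states and θ start at zero (the quiescent fixed point).
There is no refractory period.  The production engine is a compiled
(numba) loop implementing exactly this arithmetic; a pure-numpy
reference implementation defines the semantics and the two are compared
step-for-step in the test suite (identical spike lists, state agreement
at ~10⁻¹³ over thousands of steps).  All randomness comes from named
substreams of one master seed (connectivity, clusters, initial state,
schedules), so identical configurations reproduce byte-identical spike
tables and any single component can be varied in isolation.

dt = 0.05 ms was checked by step-halving and against a dt/100 reference
on a constant-drive neuron (rate changes < 1%); the V_peak clip removes
the EIF stiffness at spike onset.

## Protocols

Training presents one of Q stimuli (uniformly chosen) every 2 s for
500 ms at h_st = 0.5 mV/ms to that stimulus's target set; the session
lasts 30·Q presentation periods (10 min for the basic Q = 10 network),
scaling linearly with Q.  An option draws exponential inter-onset
intervals at the same mean instead of the fixed period.  Perturbation
sessions deliver 200 ms stimuli at Poisson times (mean interval 10 s)
under three scenarios: fresh random Bernoulli(f) target sets each time;
a 50/50 mixture of random sets and a second fixed stimulus set; or the
second set only (retraining).  Overlapping events add their currents.
Plasticity stays on throughout unless explicitly disabled.

Cluster membership is an independent Bernoulli(f) draw per
(stimulus, neuron) — the binomial spread of cluster sizes (80 ± 8.4 in
the basic network) follows from this choice rather than fixed-size
sampling.  Network scaling keeps either the mean cluster size fixed
(Q = N/100, f = 1/Q) or grows clusters as √N (Q = round(√(N/10))),
both meeting the basic network at N = 1000.

## Analysis

Firing rates are causal 50 ms boxcar counts on a 10 ms grid (the window
resolves ~250 ms states while smoothing single spikes; both knobs are
configuration fields — the estimator is a package choice).  Overlaps
m_q = Σ η_q,i ν_i / Σ ν_i are set to 0 when the network is silent.
State segments are maximal runs of samples with m_q strictly above 0.5,
with no smoothing or debouncing; segments touching a recording boundary
are flagged and excluded from duration statistics (they bias the mean).
The exponentiality diagnostic is |sd/mean − 1|.  Weight classes: a
plastic synapse is class 1 if its endpoints share at least one stimulus
of the training-time cluster map (remapping experiments must pass the
second map explicitly to re-class).  N-scaled drift curves are forward
differences of w_C over snapshot intervals multiplied by N.

## Mean-field numerics

The simplified model partitions N_E into Q equal, non-overlapping
clusters; intra-cluster weights have moments (μ₊, σ₊) on [0, w_max = 4
mV], inter-cluster weights are the constant w₋ = 0.005 mV (the
pre-training w_EE; configurable).  Moments above σ_max(μ) =
√(w_max·μ − μ²) are impossible for any distribution on the support and
are masked as forbidden.  Input moments follow the diffusion
approximation with instantaneous synapses; the finite τ_syn of the
simulations is a known source of quantitative mismatch.

F(μ, s) integrates the stationary Fokker–Planck density backward from
the absorbing boundary at V_peak to V_lb = −30 mV in steps of dV =
0.01 mV with unit flux above the reinjection point V_r, using a
per-cell integrating-factor step; the rate is the inverse probability
mass.  Halving dV or lowering V_lb by 10 mV changes rates by < 0.1%.
Strong-drift cells use the drift-limit density 1/F; when the mass
diverges at vanishing noise the rate is returned as 0.  The
self-consistent rates are found by damped fixed-point iteration
(damping 0.1, tolerance 10⁻⁶ sp/s, ≤ 10⁴ iterations) over the distinct
populations of the ansatz (uniform: E, I; one-active: active cluster,
Q−1 inactive clusters, I).  Within each outer step the inhibitory rate
is equilibrated exactly by a 1-D Brent solve — inhibition is the fast
stabilizing variable, and letting it lag the excitatory update makes
the plain iteration oscillate for strong clustering.  Branches whose
rates exceed 10⁴ sp/s are flagged non-converged: with no refractory
period the EIF transfer is unbounded, so beyond a certain μ₊ no bounded
active solution exists.  Bistability is probed from two initial
conditions (active cluster at 1 and at 50 sp/s); the landscape reports
the larger converged active rate per (μ, σ) cell, its active/inactive
phase label (difference > 1 sp/s), and per-cell failures.

## What the synthetic conditions do and do not show

All inputs are generated by the package itself (random connectivity,
Bernoulli clusters, seeded schedules); there is no external data.  The
reduced-scale test condition (N = 1000, Q = 4, 2 simulated minutes of
training, 60 s of ongoing activity) keeps the full suite within a
desktop budget; it demonstrates cluster formation (w₁ ≫ w₀) and
metastable switching, but not the slow post-training drift, the 1/N
scaling of Δw, or duration statistics converged over hours — those
require the full-scale script (`scripts/reproduce_basic.py`) and the
multi-hour protocols the engine supports.  The mean-field model further
idealizes the network (non-overlapping clusters, delta synapses, one
active cluster at a time), so its landscape locates phases and the
instability line rather than predicting simulation rates exactly.

## Known limitations

No conductance-based synapses, adaptation currents, short-term or
inhibitory plasticity (deliberately outside the model).  The one-step
spike delivery delay is an integration choice, not biology.  The
Euler–Maruyama oracle and the Fokker–Planck solver share the diffusion
idealization; they are independent numerically, not physically.
Landscape cells near the runaway boundary depend on the 10⁴ sp/s guard
rather than on network biophysics.
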