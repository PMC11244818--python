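import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from mpnet import NeuronParams, PlasticityParams, apply_presynaptic_spike, t_half
from mpnet.core import DriveVector, NetworkState, membrane_step
from mpnet.plasticity import (PlasticityState, exp_voltage_term, filter_step,
                              threshold_step)

NEURON = NeuronParams()
PLAST = PlasticityParams()


def ode_half_time(delta: float, tau_theta: float) -> float:
    """Independent oracle: integrate tau*dtheta/dt = tanh(delta - theta)
    and locate the theta = delta/2 crossing."""
    sol = solve_ivp(lambda t, th: np.tanh(delta - th) / tau_theta,
                    (0.0, 100.0 * tau_theta), [0.0], dense_output=True,
                    rtol=1e-10, atol=1e-13, max_step=tau_theta / 10)
    return brentq(lambda t: sol.sol(t)[0] - delta / 2, 1e-9, 100.0 * tau_theta)


class TestHalfTime:
    @pytest.mark.parametrize("delta", [0.01, 0.05, 0.3, 1.0, 3.0, 5.0, 10.0])
    def test_closed_form_matches_ode_oracle(self, delta):
        assert t_half(delta, 500.0) == pytest.approx(
            ode_half_time(delta, 500.0), rel=1e-2)

    def test_small_delta_limit_is_tau_ln2(self):
        assert t_half(1e-4, 500.0) == pytest.approx(500.0 * np.log(2), rel=1e-4)

    def test_large_delta_grows_linearly(self):
        # T_half ~ tau * delta / 2 for delta > 3
        for d in (4.0, 6.0, 10.0):
            assert t_half(d, 1.0) == pytest.approx(d / 2, rel=0.2)

    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_delta(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert t_half(hi, 500.0) >= t_half(lo, 500.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            t_half(0.0, 500.0)
        with pytest.raises(ValueError):
            t_half(-1.0, 500.0)


class TestThresholdStep:
    def test_fixed_point_has_zero_velocity(self):
        th = 1.7
        out = threshold_step(th, 1.2, 0.5 / PLAST.gamma, PLAST, dt=0.05)
        assert out == pytest.approx(th, abs=1e-15)

    @pytest.mark.parametrize("delta", [0.1, 3.0])
    def test_euler_integration_reaches_half_at_closed_form_time(self, delta):
        # normalized threshold equation (unit amplitude and gain)
        params = PlasticityParams(theta_a=1.0, g=1.0, gamma=0.0,
                                  tau_theta=500.0)
        dt, th, t = 0.05, 0.0, 0.0
        target = delta / 2
        while th < target:
            th = threshold_step(th, delta, 0.0, params, dt)
            t += dt
        assert t == pytest.approx(t_half(delta, 500.0), rel=2e-2)


class TestFilters:
    def test_v_tilde_converges_to_constant_drive(self):
        ps = PlasticityState.zeros(1)
        V = np.array([10.0])  # exponential term exp(-10) mV
        c = float(exp_voltage_term(V, NEURON)[0])
        for _ in range(20000):  # 1000 ms >> tau_v
            ps = filter_step(ps, V, np.zeros(1, bool), PLAST, NEURON, 0.05)
        assert ps.v_tilde[0] == pytest.approx(c, rel=1e-4)

    def test_s_tilde_pure_decay(self):
        ps = PlasticityState(np.zeros(1), np.array([0.02]), np.zeros(1))
        for _ in range(int(500 / 0.05)):
            ps = filter_step(ps, np.zeros(1), np.zeros(1, bool), PLAST,
                             NEURON, 0.05)
        assert ps.s_tilde[0] == pytest.approx(0.02 * np.exp(-500 / 1000),
                                              rel=1e-12)

    def test_s_tilde_tracks_periodic_rate(self):
        # spikes every 10 ms -> rate 0.1/ms; after >> tau_s the filter
        # average equals the rate
        ps = PlasticityState.zeros(1)
        dt = 0.05
        vals = []
        for k in range(int(8000 / dt)):
            spiked = np.array([k % 200 == 0])
            ps = filter_step(ps, np.zeros(1), spiked, PLAST, NEURON, dt)
            if k * dt > 6000:
                vals.append(ps.s_tilde[0])
        assert np.mean(vals) == pytest.approx(0.1 / 1.0, rel=2e-2)


class TestWeightUpdate:
    def test_no_change_at_threshold(self):
        assert apply_presynaptic_spike(0.3, 1.0, 1.0, PLAST) == 0.3

    def test_ltp_at_zero_weight_is_a_ltp(self):
        # attenuation factor is 1 at w = 0
        assert apply_presynaptic_spike(0.0, 2.0, 1.0, PLAST) == \
            pytest.approx(PLAST.A_LTP)

    def test_ltd_clamps_at_zero(self):
        # raw update 0.01 - 0.015 < 0 is clamped to preserve Dale's law
        assert apply_presynaptic_spike(0.01, 1.0, 2.0, PLAST) == 0.0

    def test_ltd_strength(self):
        out = apply_presynaptic_spike(1.0, 1.0, 2.0, PLAST)
        assert out == pytest.approx(1.0 - PLAST.A_LTD)

    def test_attenuation_ratio(self):
        d1 = apply_presynaptic_spike(1.0, 2.0, 1.0, PLAST) - 1.0
        d10 = apply_presynaptic_spike(10.0, 2.0, 1.0, PLAST) - 10.0
        assert d10 / d1 == pytest.approx(np.exp(-PLAST.beta * 99.0))

    def test_exactly_one_term_active(self):
        up = apply_presynaptic_spike(0.5, 1.5, 1.0, PLAST)
        down = apply_presynaptic_spike(0.5, 1.0, 1.5, PLAST)
        assert up > 0.5 > down

    def test_nonnegative_under_many_random_sequences(self, rng):
        # 10^4 synapses x 100 sequential presynaptic spikes with random
        # postsynaptic conditions: no weight ever goes negative
        w = rng.uniform(0, 4, size=10_000)
        for _ in range(100):
            v = rng.uniform(0, 150, size=w.size)
            th = rng.uniform(0, 150, size=w.size)
            w = apply_presynaptic_spike(w, v, th, PLAST)
            assert (w >= 0).all()

    def test_rejects_negative_weight(self):
        with pytest.raises(ValueError):
            apply_presynaptic_spike(-0.1, 1.0, 0.0, PLAST)


def _drive_single_neuron(pulses, total_ms, dt=0.05, pulse_amp=20.0):
    """Single E neuron integrated with the reference steps; returns the
    per-step plasticity kernel A_LTP*[v-th]+ - A_LTD*[th-v]+ and spikes."""
    state = NetworkState(0.0, np.zeros(1), np.zeros(1), np.zeros(1),
                         np.zeros(1, bool), 1)
    ps = PlasticityState.zeros(1)
    kern, nspikes = [], 0
    for k in range(int(total_ms / dt)):
        t = k * dt
        amp = pulse_amp if any(a <= t < b for a, b in pulses) else 0.0
        state = membrane_step(state, NEURON,
                              DriveVector(np.zeros(1), np.array([amp])), dt)
        nspikes += int(state.spiked[0])
        ps = filter_step(ps, state.V_pre, state.spiked, PLAST, NEURON, dt)
        d = ps.v_tilde[0] - ps.theta[0]
        kern.append(PLAST.A_LTP * max(d, 0.0) - PLAST.A_LTD * max(-d, 0.0))
    return np.array(kern), nspikes


class TestPlasticityWindows:
    def test_single_spike_gives_short_ltp_then_longer_ltd_window(self):
        # one isolated postsynaptic spike: v_tilde - theta goes positive
        # (short LTP window) then negative (longer LTD window), and the
        # expected weight change from a presynaptic train sampling the
        # kernel at a typical ongoing rate (1 spike/s) is negligible
        # against trained efficacies (~0.5 mV)
        dt = 0.05
        kern, nspikes = _drive_single_neuron([(200.0, 202.0)], 3000.0)
        assert nspikes == 1
        i_pos = np.flatnonzero(kern > 1e-9)
        i_neg = np.flatnonzero(kern < -1e-9)
        assert i_pos.size and i_neg.size
        assert i_pos[0] < i_neg[0]              # LTP window first
        assert i_neg.size > i_pos.size          # and it is the shorter one
        expected_dw = abs(kern.sum() * dt) * 1e-3  # 1 Hz in 1/ms
        assert expected_dw < 5e-3

    def test_sustained_firing_turns_ltp_into_ltd(self):
        # prolonged high firing drives theta above v_tilde through the
        # gamma*s_tilde term: late updates are depressing
        pulses = [(200.0 + k * 10, 205.0 + k * 10) for k in range(400)]
        kern, nspikes = _drive_single_neuron(pulses, 5000.0, pulse_amp=8.0)
        assert nspikes > 100
        late = kern[int(4000 / 0.05):]
        assert late.sum() < 0
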