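"""Hodgkin-Huxley afferent: rate functions, coupled integration, spikes."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fishbone.neuron import (
    CoupledState,
    HHParams,
    NeuronState,
    SpikeTrainSet,
    detect_spikes,
    hh_rates,
    hh_rhs,
    integrate_fiber,
    receptor_current,
    resting_state,
    rk4_step,
)
from fishbone.stimulus import FishbonePattern, ScanConfig, pin_trace
from fishbone.transduction import (
    ChannelParams,
    ChannelState,
    channel_rhs,
    channel_stimulus,
    conductance,
)

HH = HHParams()
CH = ChannelParams()


class TestRates:
    def test_alpha_m_at_zero(self):
        am = hh_rates(0.0, HH)[0]
        assert am == pytest.approx(0.1 * 25 / (np.exp(2.5) - 1.0), rel=1e-12)
        assert am == pytest.approx(0.22356, abs=1e-5)

    def test_removable_singularities(self):
        assert hh_rates(25.0, HH)[0] == pytest.approx(1.0)          # A1*C1
        assert hh_rates(10.0, HH)[2] == pytest.approx(0.1)          # A2*C2
        # continuity just off the singular points
        assert hh_rates(25.0 + 1e-9, HH)[0] == pytest.approx(1.0, rel=1e-6)

    def test_beta_m_at_zero(self):
        assert hh_rates(0.0, HH)[1] == pytest.approx(4.0)

    def test_vectorized(self):
        v = np.array([0.0, 25.0, 50.0])
        am = hh_rates(v, HH)[0]
        assert am.shape == (3,)
        assert am[1] == pytest.approx(1.0)


class TestReceptorCurrent:
    def test_zero_conductance(self):
        assert receptor_current([0.0, 0.0, 0.0, 0.0], 0.0, HH) == 0.0

    def test_single_receptor_at_rest_is_inward(self):
        assert receptor_current([1.0], 0.0, HH) == pytest.approx(-70.0)

    def test_linearity_over_receptors(self):
        single = receptor_current([0.3], 5.0, HH)
        assert receptor_current([0.3] * 4, 5.0, HH) == pytest.approx(4 * single)


class TestHHRhs:
    def test_rest_is_fixed_point(self):
        rest = resting_state(HH)
        derivs = hh_rhs(rest, 0.0, HH)
        assert all(abs(d) < 1e-9 for d in derivs)
        assert abs(rest.v) < 0.5  # 0-mV-rest convention

    def test_term_dropout_without_gates(self):
        state = NeuronState(v=5.0, m=0.0, n=0.0, h_gate=0.5)
        dv = hh_rhs(state, 0.0, HH)[0]
        assert dv == pytest.approx(-HH.g_L * (5.0 - HH.v_L) / HH.C_m)

    def test_gate_boundary_flows_inward(self):
        state = NeuronState(v=10.0, m=1.0, n=0.5, h_gate=0.5)
        dm = hh_rhs(state, 0.0, HH)[1]
        assert dm <= 0.0


class TestCoupledIntegration:
    def test_rest_state_is_near_stationary_under_rk4(self):
        # The sigma=0 channel equilibrium keeps a vanishing standing
        # conductance (p ~ 3e-5), so the coupled rest state drifts by under
        # 0.1 uV per step and the channel state not at all.
        rest = resting_state(HH)
        from fishbone.transduction import channel_equilibrium

        eq = channel_equilibrium(0.0, CH)
        state = CoupledState(
            neuron=rest,
            channels=ChannelState(p=np.full(4, eq.p), q=np.full(4, eq.q)),
        )
        new = rk4_step(state, np.zeros(4), 0.01, CH, HH)
        assert new.neuron.v == pytest.approx(rest.v, abs=2e-4)
        assert new.neuron.m == pytest.approx(rest.m, abs=1e-7)
        np.testing.assert_allclose(new.channels.p, eq.p, atol=1e-12)
        np.testing.assert_allclose(new.channels.q, eq.q, atol=1e-12)

    def test_sustained_step_spikes_within_50ms(self):
        sigma = np.full((5000, 1), 7.0)  # 50 ms of full-height contact
        v_trace, _ = integrate_fiber(sigma, 0.01, CH, HH)
        assert detect_spikes(v_trace, 40.0, 0.01).size >= 1

    def test_halving_dt_leaves_subthreshold_trajectory_unchanged(self):
        # A 1.5 um step from the zero-stimulus equilibrium evokes a
        # sub-threshold transient; halving dt must not move it perceptibly.
        from fishbone.transduction import channel_equilibrium

        rest = resting_state(HH)
        eq0 = channel_equilibrium(0.0, CH)

        def initial():
            return CoupledState(
                neuron=NeuronState(v=rest.v, m=rest.m, n=rest.n, h_gate=rest.h_gate),
                channels=ChannelState(p=np.full(1, eq0.p), q=np.full(1, eq0.q)),
            )

        sigma_coarse = np.full((10000, 1), 1.5)   # 200 ms at dt=0.02
        sigma_fine = np.full((20000, 1), 1.5)
        v_coarse, _ = integrate_fiber(sigma_coarse, 0.02, CH, HH, initial=initial())
        v_fine, _ = integrate_fiber(sigma_fine, 0.01, CH, HH, initial=initial())
        assert detect_spikes(v_coarse, 40.0, 0.02).size == 0
        assert np.max(np.abs(v_coarse - v_fine[::2])) < 1e-6

    def test_blow_up_detected(self):
        state = CoupledState(
            neuron=NeuronState(v=np.nan, m=0.1, n=0.1, h_gate=0.1),
            channels=ChannelState(p=np.zeros(1), q=np.zeros(1)),
        )
        with pytest.raises(FloatingPointError):
            rk4_step(state, np.zeros(1), 0.01, CH, HH)

    def test_matches_adaptive_reference_integrator(self):
        # Drive one afferent with a genuine rib-scan stimulus for 200 ms and
        # compare the RK4 grid solution against an adaptive Runge-Kutta
        # reference on the same sample-and-hold stimulus: every spike must
        # line up within 0.1 ms.
        pattern = FishbonePattern(Lw=4.0, L1=1.0, L2=1.0, h0=0.1)
        scan = ScanConfig(V=0.05, T=200.0, dt=0.01)
        trace = pin_trace((5.0, 0.3), pattern, scan, rp=0.4)
        sigma_steps = np.asarray(channel_stimulus(trace.h[:-1], CH))[:, None]
        dt = scan.dt

        v_trace, _ = integrate_fiber(sigma_steps, dt, CH, HH)
        ours = detect_spikes(v_trace, 40.0, dt)

        from fishbone.transduction import channel_equilibrium

        rest = resting_state(HH)
        eq = channel_equilibrium(sigma_steps[0, 0], CH)

        def rhs(t, y):
            i = min(int(t / dt), sigma_steps.shape[0] - 1)
            sigma = sigma_steps[i, 0]
            ch_state = ChannelState(p=y[4], q=y[5])
            dp, dq = channel_rhs(ch_state, sigma, CH)
            g = conductance(ch_state, CH)
            i_stim = receptor_current([g], y[0], HH)
            dv, dm, dn, dh = hh_rhs(
                NeuronState(v=y[0], m=y[1], n=y[2], h_gate=y[3]), i_stim, HH
            )
            return [dv, dm, dn, dh, dp, dq]

        t_eval = np.arange(v_trace.size) * dt
        sol = solve_ivp(
            rhs,
            (0.0, scan.T),
            [rest.v, rest.m, rest.n, rest.h_gate, eq.p, eq.q],
            method="RK45",
            max_step=dt,
            rtol=1e-8,
            atol=1e-10,
            t_eval=t_eval,
        )
        reference = detect_spikes(sol.y[0], 40.0, dt)
        assert ours.size == reference.size > 5
        assert np.max(np.abs(ours - reference)) <= 0.1

    def test_refractory_interval_bound(self):
        # A rib scan drives repeated firing; inter-event intervals must
        # respect the membrane's ~2 ms refractory period.
        pattern = FishbonePattern(Lw=4.0, L1=1.0, L2=0.4, h0=0.1)
        scan = ScanConfig(V=0.05, T=150.0, dt=0.01)
        trace = pin_trace((5.0, 0.3), pattern, scan, rp=0.4)
        sigma = np.asarray(channel_stimulus(trace.h[:-1], CH))[:, None]
        v_trace, _ = integrate_fiber(sigma, 0.01, CH, HH)
        events = detect_spikes(v_trace, 40.0, 0.01)
        assert events.size >= 2
        assert np.min(np.diff(events)) >= 2.0


class TestDetectSpikes:
    def test_constant_trace(self):
        assert detect_spikes(np.zeros(100), 40.0, 0.01).size == 0

    def test_single_crossing_time(self):
        v = np.array([0.0, 30.0, 50.0, 80.0, 30.0])
        events = detect_spikes(v, 40.0, dt=1.0)
        np.testing.assert_allclose(events, [2.0])

    def test_touching_from_below_not_counted(self):
        v = np.array([0.0, 39.9, 20.0, 39.99, 0.0])
        assert detect_spikes(v, 40.0, 1.0).size == 0

    def test_equality_counts_as_crossing(self):
        v = np.array([0.0, 40.0, 0.0])
        np.testing.assert_allclose(detect_spikes(v, 40.0, 1.0), [1.0])


class TestSpikeTrainSet:
    def test_validates_ordering_and_window(self):
        with pytest.raises(ValueError):
            SpikeTrainSet(trains=[np.array([2.0, 1.0])], T=10.0)
        with pytest.raises(ValueError):
            SpikeTrainSet(trains=[np.array([11.0])], T=10.0)

    def test_pooled_is_sorted(self):
        s = SpikeTrainSet(trains=[np.array([5.0]), np.array([1.0, 7.0])], T=10.0)
        np.testing.assert_allclose(s.pooled(), [1.0, 5.0, 7.0])
        assert s.n_events == 3
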