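"""LIF/synapse/STP integration: closed forms, bounds, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringwm import _fast
from ringwm.config import (ConnectivityParams, NetworkConfig, ProtocolParams,
                           STPParams, SynapseParams)
from ringwm.connectivity import build_profile
from ringwm.dynamics import (background_poisson, make_state, mg_block,
                             nmda_gating_step, rk2_step, simulate_batch,
                             stp_decay, stp_on_spike, total_current)
from conftest import uncoupled_config


class TestMgBlock:
    def test_hyperpolarized_attenuation(self):
        # at -70 mV the NMDA current is attenuated ~22.5-fold
        assert mg_block(-70.0) == pytest.approx(
            1 + np.exp(0.062 * 70) / 3.57, rel=1e-12)
        assert 21 < mg_block(-70.0) < 24

    def test_monotone_in_voltage(self):
        v = np.linspace(-90, 0, 50)
        assert np.all(np.diff(mg_block(v)) < 0)


class TestSTP:
    def test_single_spike_jump(self):
        u, x, drive = stp_on_spike(0.8, 1.0, U=0.8)
        assert u == pytest.approx(0.96)
        assert x == pytest.approx(0.04)
        assert drive == pytest.approx(0.96)

    def test_full_utilization(self):
        u, _, _ = stp_on_spike(0.3, 0.7, U=1.0)
        assert u == pytest.approx(1.0)

    def test_depleted_synapse_transmits_nothing(self):
        _, x, drive = stp_on_spike(0.5, 0.0, U=0.8)
        assert drive == 0.0 and x == 0.0

    def test_pre_jump_convention(self):
        _, _, drive = stp_on_spike(0.8, 1.0, U=0.8, pre_jump_u=True)
        assert drive == pytest.approx(0.8)

    @given(u=st.floats(0, 1), x=st.floats(0, 1),
           U=st.floats(0.01, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_jump_stays_in_unit_box(self, u, x, U):
        u2, x2, drive = stp_on_spike(u, x, U)
        assert 0.0 <= u2 <= 1.0
        assert 0.0 <= x2 <= 1.0 + 1e-15
        assert 0.0 <= drive <= 1.0

    def test_decay_closed_form(self):
        stp = STPParams()
        # x recovers toward 1 with tau_x = 250 ms
        _, x = stp_decay(0.8, 0.04, 250.0, stp)
        assert x == pytest.approx(1 - 0.96 * np.exp(-1), rel=1e-9)
        # u relaxes to U from anywhere
        u, _ = stp_decay(0.0, 1.0, 1e7, stp)
        assert u == pytest.approx(0.8)

    def test_fixed_point_convergence(self):
        # exponential relaxation: e-folding per tau, so ~14 tau reaches 1e-6
        stp = STPParams()
        u5, x5 = stp_decay(0.1, 0.2, 5 * max(stp.tau_u, stp.tau_x), stp)
        assert abs(u5 - stp.U) < 1e-2 and abs(x5 - 1.0) < 1e-2
        u, x = stp_decay(0.1, 0.2, 15 * max(stp.tau_u, stp.tau_x), stp)
        assert abs(u - stp.U) < 1e-6 and abs(x - 1.0) < 1e-6


class TestNMDAGating:
    def test_pure_decay(self):
        syn = SynapseParams()
        s, y = 0.5, 0.0
        for _ in range(100):
            s, y = nmda_gating_step(s, y, 0.0, 1.0, syn)
        assert s == pytest.approx(0.5 * np.exp(-1.0), rel=1e-4)

    def test_spike_jump_then_rise_decay(self):
        syn = SynapseParams()
        s, y = nmda_gating_step(0.0, 0.0, 0.96, 0.02, syn)
        assert y == pytest.approx(0.96, rel=1e-12)  # jump lands after decay
        s2, y2 = nmda_gating_step(s, y, 0.0, 2.0, syn)
        assert y2 == pytest.approx(0.96 * np.exp(-1.0), rel=1e-9)
        assert 0 < s2 < 1

    def test_saturation_below_one(self):
        # sustained drive saturates s at alpha*y*tau_S/(1 + alpha*y*tau_S) < 1
        syn = SynapseParams()
        s, y = 0.0, 0.0
        for _ in range(20000):
            s, y = nmda_gating_step(s, y, 0.05, 0.02, syn)
        assert 0.9 < s < 1.0


class TestBackgroundPoisson:
    def test_zero_rate(self):
        rng = np.random.default_rng(0)
        assert background_poisson(0.0, 0.02, rng, 100).sum() == 0

    def test_mean_matches_poisson_law(self):
        rng = np.random.default_rng(1)
        lam = 1.0 * 0.02
        counts = background_poisson(1.0, 0.02, rng, 10 ** 6)
        se = np.sqrt(lam / 10 ** 6)
        assert abs(counts.mean() - lam) < 3 * se

    def test_variance_matches_mean(self):
        rng = np.random.default_rng(2)
        counts = background_poisson(1.0, 0.02, rng, 10 ** 6)
        assert counts.var() == pytest.approx(0.02, rel=0.02)


class TestSingleNeuron:
    def test_resting_fixed_point(self, tiny_config):
        prof = build_profile(tiny_config.connectivity)
        res = simulate_batch(tiny_config, prof, [0], dtype=np.float64)
        assert res.spike_t.size == 0

    @pytest.mark.parametrize("I", [0.55, 0.8])
    def test_lif_isi_closed_form(self, I):
        cfg = uncoupled_config()
        prof = build_profile(cfg.connectivity)
        res = simulate_batch(cfg, prof, [0],
                             extra_current=np.full(4, I),
                             dtype=np.float64)
        t, n = res.trial_raster(0)
        isi = np.diff(t[n == 0])
        nE = cfg.neuron_E
        g, C = nE.g_L, nE.C_m
        T = nE.tau_ref + (C / g) * np.log(
            (I - g * (nE.V_res - nE.V_L)) / (I - g * (nE.V_th - nE.V_L)))
        assert isi.mean() == pytest.approx(T, rel=0.01)

    def test_dt_convergence_single_neuron(self):
        # subthreshold trajectory: halving dt changes V by < 0.01 mV RMS
        trajs = {}
        for dt in (0.02, 0.01):
            cfg = uncoupled_config(t_end=600.0)
            cfg.sim.dt = dt
            cfg.sim.record_V = True
            prof = build_profile(cfg.connectivity)
            res = simulate_batch(cfg, prof, [0],
                                 extra_current=np.full(4, 0.4),
                                 dtype=np.float64)
            trajs[dt] = res.V_samples[0, :, 0].astype(float)
        diff = trajs[0.02] - trajs[0.01]
        assert np.sqrt(np.mean(diff ** 2)) < 0.01

    def test_refractory_clamp(self):
        cfg = uncoupled_config()
        prof = build_profile(cfg.connectivity)
        res = simulate_batch(cfg, prof, [0],
                             extra_current=np.full(4, 2.0),
                             dtype=np.float64)
        t, n = res.trial_raster(0)
        isi = np.diff(t[n == 0])
        assert isi.min() >= cfg.neuron_E.tau_ref


class TestCurrents:
    def test_reversal_potentials(self):
        cfg = NetworkConfig()
        cfg.connectivity = ConnectivityParams(N_E=8, N_I=2)
        prof = build_profile(cfg.connectivity)
        st = make_state(cfg, 1)
        st.s_NMDA[:] = 0.5
        st.s_AMPA_n[:] = 2.0
        st.s_GABA[:] = 1.0
        # at V = V_E = 0 both excitatory currents vanish
        st.V[:8] = 0.0
        I_E, _ = total_current(st, cfg, prof)
        gaba_only = -(0.0 - cfg.synapse.V_I) * \
            (cfg.connectivity.G_IE_GABA * 1e-3 / 2) * 2.0
        np.testing.assert_allclose(I_E[:, 0], gaba_only, rtol=1e-9)
        # at V = V_I the GABA current vanishes
        st.V[:] = cfg.synapse.V_I
        st.s_AMPA_n[:] = 0.0
        st.s_NMDA[:] = 0.0
        I_E, I_I = total_current(st, cfg, prof)
        np.testing.assert_allclose(I_E, 0.0, atol=1e-12)
        np.testing.assert_allclose(I_I, 0.0, atol=1e-12)

    def test_excitation_depolarizes(self):
        cfg = NetworkConfig()
        cfg.connectivity = ConnectivityParams(N_E=8, N_I=2)
        prof = build_profile(cfg.connectivity)
        st = make_state(cfg, 1)
        st.s_NMDA[:] = 0.3
        I_E, I_I = total_current(st, cfg, prof)
        assert np.all(I_E > 0) and np.all(I_I > 0)


class TestNetworkIntegration:
    def test_rk2_step_matches_batch_step(self):
        cfg = uncoupled_config(poisson_rate=0.0)
        prof = build_profile(cfg.connectivity)
        st = make_state(cfg, 1)
        st.V[:4] = -55.0
        spk_E, spk_I = rk2_step(st, cfg, prof)
        assert st.t == cfg.sim.dt
        assert not spk_E.any() and not spk_I.any()

    def test_determinism_same_seed(self):
        cfg = NetworkConfig()
        cfg.protocol = ProtocolParams(t_cue_on=10, t_cue_off=40, t_end=150.0)
        prof = build_profile(cfg.connectivity)
        cue = np.zeros((512, 1))
        cue[250:260] = 0.5
        r1 = simulate_batch(cfg, prof, [7], cue_profiles=cue)
        r2 = simulate_batch(cfg, prof, [7], cue_profiles=cue)
        np.testing.assert_array_equal(r1.spike_t, r2.spike_t)
        np.testing.assert_array_equal(r1.spike_neuron, r2.spike_neuron)

    def test_trial_reproducible_across_batch_composition(self):
        cfg = NetworkConfig()
        cfg.protocol = ProtocolParams(t_cue_on=10, t_cue_off=40, t_end=120.0)
        prof = build_profile(cfg.connectivity)
        cue = np.zeros((512, 3))
        cue[100:120] = 0.4
        rb = simulate_batch(cfg, prof, [3, 4, 5], cue_profiles=cue)
        rs = simulate_batch(cfg, prof, [4], cue_profiles=cue[:, :1])
        tb, nb = rb.trial_raster(1)
        ts, ns = rs.trial_raster(0)
        np.testing.assert_array_equal(tb, ts)
        np.testing.assert_array_equal(nb, ns)

    @pytest.mark.skipif(not _fast.HAVE_NUMBA, reason="numba not installed")
    def test_engines_equivalent(self):
        cfg = NetworkConfig()
        cfg.protocol = ProtocolParams(t_cue_on=10, t_cue_off=40, t_end=120.0)
        prof = build_profile(cfg.connectivity)
        cue = np.zeros((512, 2), np.float32)
        cue[100:130] = 0.5
        ra = simulate_batch(cfg, prof, [11, 12], cue_profiles=cue,
                            engine="numba")
        rb = simulate_batch(cfg, prof, [11, 12], cue_profiles=cue,
                            engine="numpy", dtype=np.float32)
        def spikes(r, t_max=None):
            sel = slice(None) if t_max is None else r.spike_t <= t_max
            return set(zip(r.spike_t[sel].tolist(),
                           r.spike_neuron[sel].tolist(),
                           r.spike_trial[sel].tolist()))
        # identical update rules: early activity (bump ignition) matches
        # spike for spike; over the full window float32 rounding noise may
        # flip occasional threshold crossings
        assert spikes(ra, 60.0) == spikes(rb, 60.0)
        ka, kb = spikes(ra), spikes(rb)
        assert len(ka ^ kb) <= max(2, 0.05 * len(ka | kb))

    def test_state_bounds_during_activity(self):
        cfg = NetworkConfig()
        cfg.protocol = ProtocolParams(t_cue_on=10, t_cue_off=60, t_end=300.0)
        cfg.sim.record_stp = True
        prof = build_profile(cfg.connectivity)
        cue = np.zeros((512, 1))
        cue[180:220] = 0.6
        res = simulate_batch(cfg, prof, [1], cue_profiles=cue)
        assert np.all(res.u_samples >= 0) and np.all(res.u_samples <= 1)
        assert np.all(res.x_samples >= -1e-6) and np.all(res.x_samples <= 1)

    def test_no_stp_drive_is_constant_one(self):
        # with plasticity disabled u, x are untouched
        cfg = NetworkConfig()
        cfg.stp.enabled = False
        cfg.sim.record_stp = True
        cfg.protocol = ProtocolParams(t_cue_on=10, t_cue_off=60, t_end=200.0)
        prof = build_profile(cfg.connectivity)
        cue = np.zeros((512, 1))
        cue[180:220] = 0.6
        res = simulate_batch(cfg, prof, [1], cue_profiles=cue)
        assert np.all(res.u_samples == pytest.approx(cfg.stp.U))
        assert np.all(res.x_samples == 1.0)
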