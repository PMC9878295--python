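"""Rate estimation, bump segmentation, population-vector decoding, fades."""

import numpy as np
import pytest

from ringwm.config import DecodeParams
from ringwm.connectivity import preferred_angles
from ringwm.decoding import (decode_angle, decode_trial, detect_fade,
                             estimate_rates, make_report, segment_bumps)
from ringwm.fixtures import make_fixture


def circ_diff(a, b):
    return (a - b + 180.0) % 360.0 - 180.0


class TestEstimateRates:
    def test_single_spike_window_rate(self):
        rm = estimate_rates([100.0], [3], N_E=8, t_end=200.0, window=50.0,
                            smooth_sigma=0.0)
        # 1 spike / 50 ms = 20 Hz while the spike is inside the window
        i = np.searchsorted(rm.times, 100.0)
        assert rm.r[3, i] == pytest.approx(20.0)
        assert rm.r[3, i + 49] == pytest.approx(20.0)
        assert rm.r[3, i + 50] == 0.0       # spike left the causal window
        assert rm.r[3, i - 1] == 0.0        # causality: nothing before

    def test_other_neurons_untouched(self):
        rm = estimate_rates([100.0], [3], N_E=8, t_end=200.0,
                            smooth_sigma=0.0)
        assert rm.r[[0, 1, 2, 4, 5, 6, 7]].sum() == 0

    def test_empty_raster(self):
        rm = estimate_rates([], [], N_E=16, t_end=100.0)
        assert rm.r.shape == (16, 100) and rm.r.sum() == 0

    def test_constant_poisson_rate_recovered(self, rng):
        n, t_end, rate = 32, 5000.0, 30.0
        n_sp = rng.poisson(rate * t_end / 1000.0 * n)
        t = rng.uniform(0, t_end, n_sp)
        neu = rng.integers(0, n, n_sp)
        rm = estimate_rates(t, neu, N_E=n, t_end=t_end, smooth_sigma=0.0)
        est = rm.r[:, 100:].mean()
        assert est == pytest.approx(rate, rel=0.1)


class TestSegmentation:
    theta = preferred_angles(360)

    def rates_with_arcs(self, arcs, level=30.0):
        r = np.zeros(360)
        for lo, hi in arcs:
            r[lo:hi] = level
        return r

    def test_single_arc_single_stimulus(self):
        r = self.rates_with_arcs([(80, 100)])
        seg = segment_bumps(r, self.theta, [90.0])
        assert seg.alive[0]
        np.testing.assert_array_equal(np.sort(seg.subpopulations[0]),
                                      np.arange(80, 100))

    def test_two_arcs_nearest_assignment(self):
        # arcs near 90 and 270; stimuli at 85 and 265
        r = self.rates_with_arcs([(80, 100), (260, 280)])
        seg = segment_bumps(r, self.theta, [85.0, 265.0])
        assert seg.alive.all()
        assert 85 in seg.subpopulations[0]
        assert 265 in seg.subpopulations[1]

    def test_all_subthreshold_faded(self):
        r = np.full(360, 1.5)
        seg = segment_bumps(r, self.theta, [10.0, 200.0])
        assert not seg.alive.any()
        assert all(sp.size == 0 for sp in seg.subpopulations)

    def test_gap_bridging(self):
        r = self.rates_with_arcs([(80, 90), (92, 100)])  # 2-neuron gap
        seg = segment_bumps(r, self.theta, [90.0], gap_tol=3)
        assert seg.subpopulations[0].size == 20
        seg2 = segment_bumps(r, self.theta, [90.0], gap_tol=0)
        assert seg2.subpopulations[0].size in (10, 8)

    def test_wraparound_arc(self):
        r = self.rates_with_arcs([(350, 360), (0, 10)])
        seg = segment_bumps(r, self.theta, [0.0])
        assert seg.subpopulations[0].size == 20

    def test_scaling_invariance(self):
        r = self.rates_with_arcs([(80, 100)], level=30.0)
        seg1 = segment_bumps(r, self.theta, [90.0], baseline=2.0)
        seg2 = segment_bumps(10 * r, self.theta, [90.0], baseline=20.0)
        np.testing.assert_array_equal(seg1.subpopulations[0],
                                      seg2.subpopulations[0])

    def test_merged_bumps_share_arc(self):
        r = self.rates_with_arcs([(120, 140)])
        seg = segment_bumps(r, self.theta, [125.0, 138.0])
        np.testing.assert_array_equal(seg.subpopulations[0],
                                      seg.subpopulations[1])


class TestDecodeAngle:
    theta = preferred_angles(360)

    def test_single_neuron(self):
        r = np.zeros(360)
        r[119] = 10.0  # neuron 120 prefers 120 deg
        assert decode_angle(r, self.theta, np.array([119])) \
            == pytest.approx(120.0)

    def test_two_neuron_symmetry(self):
        r = np.zeros(360)
        r[[79, 99]] = 5.0  # 80 and 100 deg
        ang = decode_angle(r, self.theta, np.array([79, 99]))
        assert ang == pytest.approx(90.0)

    def test_empty_or_silent_undefined(self):
        r = np.zeros(360)
        assert np.isnan(decode_angle(r, self.theta, np.array([], dtype=int)))
        assert np.isnan(decode_angle(r, self.theta, np.array([5, 6])))

    def test_brute_force_oracle(self, rng):
        # the decode equals an independently coded weighted circular mean
        theta = preferred_angles(512)
        for _ in range(1000):
            sub = rng.choice(512, rng.integers(2, 40), replace=False)
            r = np.zeros(512)
            r[sub] = rng.random(sub.size) * 50
            got = decode_angle(r, theta, sub)
            s = c = 0.0
            for j in sub:                      # explicit accumulation
                s += r[j] * np.sin(theta[j])
                c += r[j] * np.cos(theta[j])
            want = np.rad2deg(np.arctan2(s, c)) % 360.0
            assert abs(circ_diff(got, want)) < 1e-9

    def test_rotation_equivariance(self, rng):
        theta = preferred_angles(512)
        r = np.zeros(512)
        sub = np.arange(100, 140)
        r[sub] = rng.random(40) * 30
        a0 = decode_angle(r, theta, sub)
        for k in (3, 57, 200):
            a1 = decode_angle(np.roll(r, k), theta, (sub + k) % 512)
            assert circ_diff(a1, a0 + k * 360.0 / 512) \
                == pytest.approx(0.0, abs=1e-9)


class TestFadeAndReport:
    def test_silent_subpop_fades(self):
        rm = estimate_rates([], [], N_E=16, t_end=500.0)
        assert detect_fade(rm, np.arange(4), 500.0)

    def test_active_bump_not_faded(self):
        (t, n), truth = make_fixture("stable_bump", seed=1, t_end=800.0)
        rm = estimate_rates(t, n, truth["N_E"], 800.0)
        sub = np.arange(270, 300)  # around 200 deg for N=512
        assert not detect_fade(rm, sub, 800.0)

    def test_truncated_bump_fades(self):
        (t, n), truth = make_fixture("fading_bump", seed=2, t_end=3000.0,
                                     fade_time=1500.0, bg_rate=0.1)
        rm = estimate_rates(t, n, truth["N_E"], 3000.0)
        sub = np.arange(260, 310)
        assert detect_fade(rm, sub, 3000.0)
        assert not detect_fade(rm, sub, 1400.0)

    def test_report_passthrough_and_guess(self, rng):
        assert make_report(212.0, False, rng) == 212.0
        # faded reports are uniform: chi-square over 18 bins
        guesses = [make_report(np.nan, True, rng) for _ in range(9000)]
        h, _ = np.histogram(guesses, bins=np.arange(0, 361, 20))
        chi2 = ((h - 500.0) ** 2 / 500.0).sum()
        from scipy.stats import chi2 as chi2_dist
        assert chi2 > 0
        assert chi2_dist.sf(chi2, 17) > 1e-3


class TestDecodeTrial:
    def test_stable_bump_recovered(self):
        (t, n), truth = make_fixture("stable_bump", seed=3, t_end=1000.0,
                                     center_deg=200.0)
        rm = estimate_rates(t, n, truth["N_E"], 1000.0)
        theta = preferred_angles(truth["N_E"])
        dec, alive, faded, reports = decode_trial(
            rm, theta, [200.0], DecodeParams(),
            np.random.default_rng(0))
        assert not faded[0]
        assert abs(circ_diff(reports[0], 200.0)) < 5.0
        # time-averaged decode is unbiased to ~degree scale
        tail = dec[0, rm.times > 500.0]
        assert abs(circ_diff(np.nanmean(tail), 200.0)) < 2.0

    def test_drifting_bump_tracked(self):
        (t, n), truth = make_fixture("drifting_bump", seed=4, t_end=2000.0,
                                     center_deg=100.0, drift_deg_per_s=20.0)
        rm = estimate_rates(t, n, truth["N_E"], 2000.0)
        theta = preferred_angles(truth["N_E"])
        dec, alive, faded, reports = decode_trial(
            rm, theta, [100.0], DecodeParams(), np.random.default_rng(0))
        assert abs(circ_diff(reports[0], truth["end_center_deg"])) < 4.0
        mid = np.searchsorted(rm.times, 1000.0)
        assert abs(circ_diff(dec[0, mid], 120.0)) < 5.0

    def test_merged_bumps_report_together(self):
        (t, n), truth = make_fixture("merged_bumps", seed=5, t_end=1000.0)
        rm = estimate_rates(t, n, truth["N_E"], 1000.0)
        theta = preferred_angles(truth["N_E"])
        dec, alive, faded, reports = decode_trial(
            rm, theta, [truth["stim1_deg"], truth["stim2_deg"]],
            DecodeParams(), np.random.default_rng(0))
        assert reports[0] == reports[1]
        assert abs(circ_diff(reports[0], truth["shared_center"])) < 3.0

    def test_faded_stimulus_gets_guess(self):
        (t, n), truth = make_fixture("uniform_noise", seed=6, t_end=600.0,
                                     bg_rate=0.2)
        rm = estimate_rates(t, n, truth["N_E"], 600.0)
        theta = preferred_angles(truth["N_E"])
        g1 = np.random.default_rng(42)
        dec, alive, faded, reports = decode_trial(
            rm, theta, [90.0], DecodeParams(), g1)
        assert faded[0]
        assert reports[0] == np.random.default_rng(42).uniform(0, 360)
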