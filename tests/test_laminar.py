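"""Depth profiles, layer assignment and speed-theta regressions."""

import numpy as np
import pytest

from thetaquant.laminar import (DepthProfile, RegressionResult, estimate_layers,
                                ripple_power_profile, speed_theta_regression,
                                theta_depth_profile)
from thetaquant.profiles import RAT
from thetaquant.session import Recording, SpeedTrace
from thetaquant.synth import GeneratorConfig, TrialSpec, generate_session
from thetaquant.theta import ThetaInstantaneous

FS = 1000.0

LOCOMOTION_RICH = TrialSpec(run_plateau_dur_range=(3.0, 5.0), intertrial_range=(1.0, 2.0))


@pytest.fixture(scope="module")
def profiled_session():
    cfg = GeneratorConfig.default("rat", duration_s=240.0, seed=17, sp_channel=15,
                                  n_cortical=4, trial_spec=LOCOMOTION_RICH)
    sess, truth = generate_session(cfg)
    prof = theta_depth_profile(sess, with_regressions=False)
    return sess, truth, prof


class TestDepthProfile:
    def test_phase_shift_recovered(self, profiled_session):
        _, truth, prof = profiled_session
        # top channel is the reference by definition
        assert prof.phase_mean_deg[0] == 0.0
        total = abs(((prof.phase_mean_deg[-1] - prof.phase_mean_deg[0]) + 180) % 360 - 180)
        assert abs(total - 180.0) <= 15.0
        # shift happens below the cell layer, not above
        hippocampal = slice(5, truth.sp_channel)
        assert np.all(np.abs(prof.phase_mean_deg[hippocampal]) < 25.0)

    def test_power_dip_at_cell_layer(self, profiled_session):
        _, truth, prof = profiled_session
        sp = truth.sp_channel
        assert prof.power_median[sp] < prof.power_median[sp - 2]
        assert prof.power_median[sp] < prof.power_median[sp + 2]

    def test_flat_profile_for_uniform_generator(self):
        cfg = GeneratorConfig.default("rat", duration_s=240.0, seed=18,
                                      n_cortical=0, sp_channel=16,
                                      theta_amp_profile=np.full(32, 60.0),
                                      phase_shift_profile=np.zeros(32),
                                      trial_spec=LOCOMOTION_RICH)
        sess, _ = generate_session(cfg)
        prof = theta_depth_profile(sess, with_regressions=False)
        assert np.nanmax(prof.power_median) / np.nanmin(prof.power_median) < 1.25

    def test_insufficient_locomotion_rejected(self, ferret_session):
        sess, _ = ferret_session
        with pytest.raises(ValueError, match="locomotion"):
            theta_depth_profile(sess, min_locomotion_s=1e6)


class TestEstimateLayers:
    @staticmethod
    def _profile(power, phase):
        n = len(power)
        return DepthProfile(channels=np.arange(n), depth_um=np.arange(n) * 100.0,
                            power_median=np.asarray(power, float),
                            power_iqr=np.zeros((2, n)),
                            phase_mean_deg=np.asarray(phase, float),
                            phase_sd_deg=np.zeros(n),
                            slope_freq=np.zeros(n), slope_power=np.zeros(n),
                            sig_freq=np.zeros(n, bool), sig_power=np.zeros(n, bool))

    def test_constructed_probe_arithmetic(self):
        power = np.full(32, 55.0)
        power[15] = 20.0
        phase = np.zeros(32)
        phase[16:19] = [60, 120, 180]
        phase[19:] = 180
        lm = estimate_layers(self._profile(power, phase))
        assert (lm.sp_channel, lm.so_channel, lm.srslm_channel) == (15, 13, 19)
        assert lm.method == "profile"

    def test_monotone_profile_falls_back_to_power_peak(self):
        power = np.linspace(20, 90, 32)
        lm = estimate_layers(self._profile(power, np.zeros(32)))
        assert lm.method == "power-peak fallback"
        assert lm.so_channel == 31
        assert lm.sp_channel is None and lm.srslm_channel is None

    def test_flat_profile_degenerate_fallback(self):
        lm = estimate_layers(self._profile(np.full(32, 50.0), np.zeros(32)))
        assert lm.method == "power-peak fallback"
        assert lm.srslm_channel is None

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            estimate_layers(self._profile(np.ones(4), np.zeros(4)))

    def test_recovery_on_generated_probe(self, profiled_session):
        _, truth, prof = profiled_session
        lm = estimate_layers(prof)
        assert lm.sp_channel == truth.sp_channel
        assert lm.so_channel == truth.so_channel
        assert lm.srslm_channel == truth.srslm_channel


class TestSpeedRegression:
    def test_slope_recovery_single_session(self):
        from thetaquant.theta import theta_for_channel
        cfg = GeneratorConfig.default("rat", duration_s=180.0, seed=205,
                                      speed_freq_slope=0.03,
                                      trial_spec=TrialSpec(intertrial_range=(3.0, 6.0)))
        sess, truth = generate_session(cfg)
        inst = theta_for_channel(sess.recording.samples[truth.so_channel],
                                 sess.species_profile, sess.recording.fs)
        res = speed_theta_regression(inst, sess.speed, "frequency")
        assert res is not None
        assert res.beta1 == pytest.approx(0.030, abs=0.005)
        assert res.p < 0.05  # few bins: the Bonferroni flag needs a wider speed range

    @staticmethod
    def _slow_speed(rng, n, lo=10.0, hi=45.0, block=250):
        """Speed that is constant within each 250 ms epoch (slow variation)."""
        return np.repeat(rng.uniform(lo, hi, n // block), block)

    def test_null_slope_not_significant(self):
        rng = np.random.default_rng(3)
        n = 120000
        v = self._slow_speed(rng, n)
        inst = ThetaInstantaneous(frequency=7.0 + 0.2 * rng.standard_normal(n),
                                  amplitude=np.ones(n), power=np.ones(n),
                                  phase=np.zeros(n), fs=FS)
        res = speed_theta_regression(inst, SpeedTrace(v, FS), "frequency")
        assert res is not None
        assert not res.significant and res.p > 0.0016

    def test_negative_power_coupling_detected(self):
        """Power decreasing with speed (as below the cell layer) yields a
        significant negative slope."""
        rng = np.random.default_rng(4)
        n = 120000
        v = self._slow_speed(rng, n)
        power = 100 - 0.8 * v + rng.standard_normal(n)
        inst = ThetaInstantaneous(frequency=np.full(n, 7.0), amplitude=np.sqrt(power),
                                  power=power, phase=np.zeros(n), fs=FS)
        res = speed_theta_regression(inst, SpeedTrace(v, FS), "power")
        assert res.beta1 < 0 and res.significant

    def test_shuffled_speed_type_one_control(self):
        """Permuting the speed labels of the epochs destroys the coupling:
        the per-channel test at its Bonferroni-corrected operating
        threshold fires at most rarely (allowing for the small-df
        approximation of the bin-median slope test)."""
        rng = np.random.default_rng(5)
        n = 60000
        v = self._slow_speed(rng, n, lo=10.0, hi=40.0)
        f = 7.0 + 0.03 * v + 0.3 * rng.standard_normal(n)
        hits = 0
        n_perm = 1000
        n_blocks = n // 250
        for _ in range(n_perm):
            order = rng.permutation(n_blocks)
            f_perm = f.reshape(n_blocks, 250)[order].ravel()
            inst = ThetaInstantaneous(frequency=f_perm, amplitude=np.ones(n),
                                      power=np.ones(n), phase=np.zeros(n), fs=FS)
            res = speed_theta_regression(inst, SpeedTrace(v, FS), "frequency")
            hits += bool(res and res.significant)
        assert hits / n_perm <= 0.01


class TestRipple:
    def test_injected_ripple_peaks_at_cell_layer(self):
        rng = np.random.default_rng(6)
        samples = 10 * rng.standard_normal((8, 30000))
        t = np.arange(2000) / FS
        burst = 40 * np.sin(2 * np.pi * 180 * t)
        samples[4, 5000:7000] += burst
        rec = Recording(samples=samples, fs=FS, channel_depth=np.arange(8) * 100.0,
                        cortical_flag=np.zeros(8, bool))
        prof = ripple_power_profile(rec)
        assert np.argmax(prof) == 4

    def test_no_ripple_content_is_flat(self):
        rng = np.random.default_rng(7)
        rec = Recording(samples=10 * rng.standard_normal((8, 30000)), fs=FS,
                        channel_depth=np.arange(8) * 100.0, cortical_flag=np.zeros(8, bool))
        prof = ripple_power_profile(rec)
        assert prof.max() / prof.min() < 1.2

    def test_band_misconfiguration_rejected(self):
        rec = Recording(samples=np.random.default_rng(0).standard_normal((2, 5000)), fs=FS,
                        channel_depth=[0, 100], cortical_flag=[False, False])
        with pytest.raises(ValueError):
            ripple_power_profile(rec, band=(250.0, 150.0))
        with pytest.raises(ValueError):
            ripple_power_profile(rec, band=(150.0, 600.0))
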