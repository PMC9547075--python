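"""Channel selection, artifact masking and tracking cleanup."""

import numpy as np
import pytest

from thetaquant.cleaning import (ArtifactMask, clean_session, clean_tracking,
                                 compute_psd, compute_speed, detect_amplitude_artifacts,
                                 histogram_mode, remove_scratch_hvs, select_channels)
from thetaquant.profiles import FERRET, RAT
from thetaquant.session import Recording, SpeedTrace, TrackingData
from thetaquant.synth import GeneratorConfig, generate_session, synthesize_tracking

FS = 1000.0


# ---------------------------------------------------------------------------
# PSD

class TestComputePsd:
    def test_sinusoid_peak_location(self):
        t = np.arange(0, 20, 1 / FS)
        freqs, psd = compute_psd(np.sin(2 * np.pi * 6 * t), FS)
        assert abs(freqs[np.argmax(psd)] - 6.0) <= FS / 4096

    def test_white_noise_is_flat_within_estimator_variance(self):
        rng = np.random.default_rng(0)
        n_seg = 2 * 60000 // 4096 - 1
        freqs, psd = compute_psd(rng.standard_normal(60000), FS, db=False)
        sel = (freqs > 10) & (freqs < 490)
        rel_sd = np.std(psd[sel]) / np.mean(psd[sel])
        assert rel_sd < 3.0 / np.sqrt(n_seg)

    def test_skewed_theta_shows_harmonic_peak(self):
        from thetaquant.synth import _skewed_wave
        t = np.arange(0, 60, 1 / FS)
        phase = 2 * np.pi * 6 * t
        freqs, psd = compute_psd(_skewed_wave(phase, np.full(t.size, 0.4)), FS)

        def peak_db(f0):
            sel = np.abs(freqs - f0) < 0.5
            return np.max(psd[sel])

        background = np.median(psd[(freqs > 15) & (freqs < 25)])
        assert peak_db(12.0) > background + 20.0  # harmonic at 2f

    def test_all_masked_input_raises(self):
        with pytest.raises(ValueError):
            compute_psd(np.full(10000, np.nan), FS)

    def test_masked_segments_are_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30000)
        x[10000:12000] = np.nan
        freqs, psd = compute_psd(x, FS, db=False)
        assert np.all(np.isfinite(psd))


# ---------------------------------------------------------------------------
# Channel selection

def _recording_from(samples):
    n = samples.shape[0]
    return Recording(samples=samples, fs=FS, channel_depth=np.arange(n) * 100.0,
                     cortical_flag=np.zeros(n, dtype=bool))


class TestSelectChannels:
    def test_low_theta_channel_excluded(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 30, 1 / FS)
        good = 50 * np.sin(2 * np.pi * 6 * t) + rng.standard_normal(t.size)
        dead = 0.05 * rng.standard_normal(t.size)
        rec = _recording_from(np.vstack([good, dead]))
        include, reasons, all_excluded = select_channels(rec, FERRET)
        assert include[0] and not include[1]
        assert reasons[1] == "low_theta"
        assert not all_excluded

    def test_mains_dominated_channel_excluded(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 30, 1 / FS)
        theta = 20 * np.sin(2 * np.pi * 6 * t)
        noisy = theta + 200 * np.sin(2 * np.pi * 50 * t) + rng.standard_normal(t.size)
        rec = _recording_from(np.vstack([theta + rng.standard_normal(t.size), noisy]))
        include, reasons, _ = select_channels(rec, FERRET)
        assert include[0] and not include[1]
        assert reasons[1] == "mains"

    def test_clean_channels_all_retained(self, ferret_session):
        sess, _ = ferret_session
        include, reasons, all_excluded = select_channels(sess.recording, FERRET)
        assert include.all() and not reasons and not all_excluded


# ---------------------------------------------------------------------------
# Amplitude artifacts

class TestAmplitudeArtifacts:
    def test_clean_session_nearly_unmasked(self, ferret_session):
        sess, _ = ferret_session
        mask = detect_amplitude_artifacts(sess.recording)
        assert mask.fraction < 0.005

    def test_injected_transient_fully_masked(self):
        rng = np.random.default_rng(4)
        samples = 30 * rng.standard_normal((4, 30000))
        typical = np.median(np.abs(samples))
        samples[:, 5000:5100] += 20 * typical
        mask = detect_amplitude_artifacts(_recording_from(samples))
        assert mask.labels["amplitude"][5000:5100].all()
        assert ("amplitude" in {lab for _, _, lab in mask.runs()})

    def test_zero_run_masked_with_own_label(self):
        rng = np.random.default_rng(5)
        samples = 30 * rng.standard_normal((4, 30000))
        samples[:, 8000:8500] = 0.0
        mask = detect_amplitude_artifacts(_recording_from(samples))
        assert mask.labels["zero"][8000:8500].all()
        assert not mask.labels["amplitude"][8100]

    def test_constant_signal_raises(self):
        with pytest.raises(ValueError):
            detect_amplitude_artifacts(_recording_from(np.ones((2, 20000))))

    def test_short_recording_raises(self):
        with pytest.raises(ValueError):
            detect_amplitude_artifacts(_recording_from(np.random.default_rng(0).standard_normal((2, 2000))))


# ---------------------------------------------------------------------------
# Scratch / HVS

class TestScratchRemoval:
    def test_recall_and_false_positives(self, rat_session_with_artifacts):
        sess, truth = rat_session_with_artifacts
        _, _, _, mask = clean_session(sess.recording, RAT)
        gt = truth.artifact_mask
        recall = (mask.mask & gt).sum() / gt.sum()
        fpr = (mask.mask & ~gt).sum() / (~gt).sum()
        assert recall >= 0.95
        assert fpr <= 0.01

    def test_quiet_cortex_gives_low_false_positive_rate(self, rat_session):
        sess, _ = rat_session
        mask = remove_scratch_hvs(sess.recording, RAT)
        assert mask.fraction < 0.02

    def test_ferret_session_is_noop_with_warning(self, ferret_session, caplog):
        import logging
        sess, _ = ferret_session
        with caplog.at_level(logging.WARNING, logger="thetaquant.cleaning"):
            mask = remove_scratch_hvs(sess.recording, FERRET)
        assert not mask.mask.any()
        assert any("cortical" in r.message for r in caplog.records)

    def test_masking_is_monotone_under_added_artifacts(self, rat_session_with_artifacts):
        """Adding artifacts can only grow the mask (OR composition)."""
        sess, _ = rat_session_with_artifacts
        m1 = detect_amplitude_artifacts(sess.recording)
        m2 = remove_scratch_hvs(sess.recording, RAT)
        combined = m1 | m2
        assert np.all(combined.mask[m1.mask])
        assert np.all(combined.mask[m2.mask])


def test_histogram_mode_is_deterministic_and_scale_aware():
    rng = np.random.default_rng(6)
    x = rng.normal(10.0, 1.0, 20000)
    m1 = histogram_mode(x)
    assert abs(m1 - 10.0) < 0.3
    assert np.isclose(histogram_mode(5 * x), 5 * m1, rtol=0.1)


# ---------------------------------------------------------------------------
# Tracking

def _constant_tracking(n=100, fps=25.0, sep=40.0):
    red = np.tile([100.0, 100.0], (n, 1))
    green = np.tile([100.0 + sep, 100.0], (n, 1))
    return TrackingData(red=red, green=green, fps=fps)


class TestTracking:
    def test_constant_positions_unchanged(self):
        raw = _constant_tracking()
        out = clean_tracking(raw)
        assert out.valid.all()
        assert np.allclose(out.red, raw.red)

    def test_single_frame_reflection_interpolated(self):
        raw = _constant_tracking(100)
        raw.red[50] += [200.0, 0.0]
        out = clean_tracking(raw)
        assert out.valid[50]
        assert np.allclose(out.red[50], [100.0, 100.0])

    def test_long_gap_not_interpolated(self):
        raw = _constant_tracking(200, fps=25.0)
        raw.valid[60:90] = False  # 1.2 s at 25 fps > 660 ms
        out = clean_tracking(raw)
        assert not out.valid[60:90].any()
        assert np.isnan(out.red[70]).all()

    def test_separation_violation_invalidated(self):
        raw = _constant_tracking(100, sep=40.0)
        raw.green[30] = raw.red[30] + [10.0, 0.0]  # LEDs 10 px apart
        out = clean_tracking(raw)
        assert np.allclose(out.red[30], [100.0, 100.0])  # interpolated back

    def test_speed_arithmetic(self):
        n, fps = 100, 25.0
        x = np.arange(n, dtype=float)  # 1 px/frame
        red = np.column_stack([x, np.zeros(n)])
        green = np.column_stack([x + 40.0, np.zeros(n)])
        speed = compute_speed(TrackingData(red=red, green=green, fps=fps), px_per_cm=1.0)
        assert np.allclose(speed.values[1:], 25.0)

    def test_stationary_leds_give_zero_speed(self):
        speed = compute_speed(_constant_tracking(), px_per_cm=4.0)
        assert np.allclose(speed.values, 0.0)

    def test_missing_px_per_cm_rejected(self):
        with pytest.raises(ValueError):
            compute_speed(_constant_tracking(), px_per_cm=None)

    def test_speed_recovered_from_synthesized_tracks(self):
        t = np.arange(0, 60, 1e-3)
        v = 15 + 10 * np.sin(2 * np.pi * t / 20)
        truth = SpeedTrace(v, 1000.0)
        tracks = synthesize_tracking(truth, fps=30.0, px_per_cm=4.0, seed=5)
        est = compute_speed(clean_tracking(tracks), 4.0, out_fs=1000.0, n_samples=v.size)
        ok = np.isfinite(est.values)
        rms = np.sqrt(np.mean((est.values[ok] - v[ok]) ** 2))
        assert rms < 1.0
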