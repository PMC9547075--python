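"""Artifact detection, channel exclusion and head-tracking cleanup.

The cleaning stage works per session: channels with too little theta
power or too much mains noise are excluded on the basis of Welch PSDs;
large-amplitude/zero/saturation artifacts are masked on all channels
from the cross-channel mean amplitude; 8-12 Hz "scratching" bursts and
high-voltage spike-wave events are removed wherever the median 6-13 Hz
Hilbert power of the *cortical* channels exceeds a mode-derived
threshold; and LED head tracking is de-glitched, gap-filled and median
smoothed before head speed is computed.

Thresholds derived from "the mode of the distribution" use a
Freedman-Diaconis histogram mode, which is deterministic and scales
with the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage, signal

from .filters import design_fir_bandpass, zero_lag_fir
from .profiles import SpeciesProfile
from .session import Recording, SpeedTrace, TrackingData

__all__ = [
    "ArtifactMask",
    "compute_psd",
    "select_channels",
    "detect_amplitude_artifacts",
    "remove_scratch_hvs",
    "clean_tracking",
    "compute_speed",
    "apply_mask",
    "clean_session",
]

log = logging.getLogger(__name__)

PSD_NFFT = 4096


def histogram_mode(x: np.ndarray) -> float:
    """Mode of a continuous sample via a Freedman-Diaconis histogram."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite samples")
    q25, q75 = np.percentile(x, [25, 75])
    width = 2.0 * (q75 - q25) * x.size ** (-1.0 / 3.0)
    if width <= 0:
        raise ValueError("degenerate (constant) distribution; cannot locate a mode")
    n_bins = max(1, int(np.ceil((x.max() - x.min()) / width)))
    counts, edges = np.histogram(x, bins=n_bins)
    k = int(np.argmax(counts))
    return 0.5 * (edges[k] + edges[k + 1])


@dataclass
class ArtifactMask:
    """Per-sample artifact mask (applied to all channels) with provenance."""

    mask: np.ndarray
    labels: Dict[str, np.ndarray] = field(default_factory=dict)
    threshold: Optional[float] = None

    def __or__(self, other: "ArtifactMask") -> "ArtifactMask":
        labels = {k: v.copy() for k, v in self.labels.items()}
        for k, v in other.labels.items():
            labels[k] = labels.get(k, np.zeros_like(v)) | v
        return ArtifactMask(self.mask | other.mask, labels)

    def runs(self) -> List[Tuple[int, int, str]]:
        """(start, stop, label) for every masked run, label by first cause."""
        out = []
        edges = np.flatnonzero(np.diff(np.concatenate(([False], self.mask, [False]))))
        for i0, i1 in edges.reshape(-1, 2):
            label = next((k for k, v in self.labels.items() if v[i0:i1].any()), "unknown")
            out.append((int(i0), int(i1), label))
        return out

    @property
    def fraction(self) -> float:
        return float(np.mean(self.mask))


# ---------------------------------------------------------------------------
# PSD


def compute_psd(x: np.ndarray, fs: float, nfft: int = PSD_NFFT,
                db: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """Welch PSD (Hanning window, 50% overlap, segment length = nfft).

    Any segment containing a masked (NaN) sample is dropped from the
    average. Raises if fewer than ``nfft`` valid samples remain.
    """
    x = np.asarray(x, dtype=float)
    step = nfft // 2
    win = signal.get_window("hann", nfft)
    scale = 1.0 / (fs * np.sum(win ** 2))
    periodograms = []
    for i0 in range(0, x.size - nfft + 1, step):
        seg = x[i0:i0 + nfft]
        if not np.all(np.isfinite(seg)):
            continue
        seg = (seg - seg.mean()) * win
        spec = np.abs(np.fft.rfft(seg)) ** 2 * scale
        spec[1:-1] *= 2.0  # one-sided
        periodograms.append(spec)
    if not periodograms:
        raise ValueError(f"need at least {nfft} contiguous valid samples for the PSD")
    pxx = np.mean(periodograms, axis=0)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    if db:
        pxx = 10.0 * np.log10(pxx + 1e-300)
    return freqs, pxx


def _band_peak_db(freqs: np.ndarray, pxx_db: np.ndarray, band) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.max(pxx_db[sel]))


def select_channels(rec: Recording, profile: SpeciesProfile):
    """Exclude channels with weak theta or dominant 50 Hz noise.

    Returns ``(include, reasons, all_excluded)``. A channel is dropped if
    its theta-band PSD peak is below the species threshold
    (reason ``low_theta``) or its 50 Hz peak exceeds the theta peak by
    more than the configured margin (reason ``mains``).
    """
    include = np.ones(rec.n_channels, dtype=bool)
    reasons: Dict[int, str] = {}
    for c in range(rec.n_channels):
        freqs, pxx = compute_psd(rec.samples[c], rec.fs)
        theta_db = _band_peak_db(freqs, pxx, profile.psd_theta_band)
        mains_db = _band_peak_db(freqs, pxx, (49.0, 51.0))
        if theta_db < profile.theta_power_exclusion_db:
            include[c] = False
            reasons[c] = "low_theta"
        elif mains_db >= theta_db + profile.mains_margin_db:
            include[c] = False
            reasons[c] = "mains"
    all_excluded = not include.any()
    if all_excluded:
        log.warning("all channels excluded; session should be dropped")
    return include, reasons, all_excluded


# ---------------------------------------------------------------------------
# Amplitude / zero / saturation artifacts


def detect_amplitude_artifacts(rec: Recording, factor: float = 10.0,
                               saturation_rail_uv: float = 2000.0,
                               pad_s: float = 0.01, min_zero_run_s: float = 0.005) -> ArtifactMask:
    """Mask large-amplitude transients, zero runs and saturation.

    The threshold is the Freedman-Diaconis mode of the across-channel
    mean absolute amplitude, multiplied by ``factor`` (default 10).
    Supra-threshold samples are masked on all channels; runs where every
    channel reads exactly zero, or any channel sits at the saturation
    rail, get their own labels.
    """
    if rec.duration < 10.0:
        raise ValueError("need at least 10 s of data to estimate the amplitude mode")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_amp = np.nanmean(np.abs(rec.samples), axis=0)
    mode = histogram_mode(mean_amp)
    threshold = factor * mode
    pad = max(1, int(round(pad_s * rec.fs)))

    amplitude = ndimage.binary_dilation(mean_amp > threshold, iterations=pad)

    zero = np.all(rec.samples == 0.0, axis=0)
    min_run = max(1, int(round(min_zero_run_s * rec.fs)))
    zero = ndimage.binary_opening(zero, structure=np.ones(min_run, dtype=bool))
    amplitude &= ~zero  # zero runs are labelled as zeros, not amplitude

    with np.errstate(invalid="ignore"):
        saturation = np.any(np.abs(rec.samples) >= saturation_rail_uv, axis=0)
    labels = {"amplitude": amplitude & ~saturation, "zero": zero, "saturation": saturation}
    mask = amplitude | zero | saturation
    return ArtifactMask(mask=mask, labels=labels, threshold=threshold)


# ---------------------------------------------------------------------------
# Scratching / HVS removal


def remove_scratch_hvs(rec: Recording, profile: SpeciesProfile,
                       pad_s: float = 0.01) -> ArtifactMask:
    """Mask scratching artifacts and putative HVS epochs.

    Protocol: zero-lag FIR band-pass (6-13 Hz, order 0.5 s) per cortical
    channel -> Hilbert power -> median across cortical channels ->
    threshold = histogram mode of that median power x the profile's
    scratch factor -> supra-threshold sections masked on all channels.
    Ferret sessions carry no cortical channels; the result is an empty
    mask with a warning.
    """
    cortical = np.flatnonzero(rec.cortical_flag)
    n = rec.n_samples
    if cortical.size == 0:
        log.warning("no cortical channels flagged; scratch/HVS removal skipped")
        return ArtifactMask(mask=np.zeros(n, dtype=bool), labels={"scratch_hvs": np.zeros(n, dtype=bool)})
    taps = design_fir_bandpass(profile.scratch_band, profile.scratch_fir_order_s, rec.fs)
    powers = np.empty((cortical.size, n))
    for i, c in enumerate(cortical):
        filt = zero_lag_fir(rec.samples[c], taps)
        bad = ~np.isfinite(filt)
        powers[i] = np.abs(signal.hilbert(np.where(bad, 0.0, filt))) ** 2
        powers[i, bad] = np.nan  # already-masked samples don't enter the stats
    median_power = np.median(powers, axis=0)
    # the filter edges leave the first/last half-order unassessed; extend the
    # nearest assessable power there so edge-adjacent bursts are not missed
    finite = np.flatnonzero(np.isfinite(median_power))
    if finite.size:
        median_power[: finite[0]] = median_power[finite[0]]
        median_power[finite[-1] + 1:] = median_power[finite[-1]]
    threshold = histogram_mode(median_power) * profile.scratch_threshold_factor
    pad = max(1, int(round(pad_s * rec.fs)))
    with np.errstate(invalid="ignore"):
        mask = ndimage.binary_dilation(median_power > threshold, iterations=pad)
    # unassessable gaps (power NaN next to already-masked data) are bridged
    # when the flanking assessable power is supra-threshold
    nan_runs = np.flatnonzero(np.diff(np.concatenate(
        ([False], ~np.isfinite(median_power), [False]))))
    for i0, i1 in nan_runs.reshape(-1, 2):
        if (i0 > 0 and mask[i0 - 1]) or (i1 < n and mask[i1 % n]):
            mask[i0:i1] = True
    return ArtifactMask(mask=mask, labels={"scratch_hvs": mask}, threshold=threshold)


def apply_mask(rec: Recording, mask: ArtifactMask) -> Recording:
    """Return a new Recording with masked samples NaN'd on every channel."""
    samples = rec.samples.copy()
    samples[:, mask.mask] = np.nan
    valid = rec.valid_mask & ~mask.mask[None, :]
    return Recording(samples=samples, fs=rec.fs, channel_depth=rec.channel_depth.copy(),
                     cortical_flag=rec.cortical_flag.copy(), valid_mask=valid)


def clean_session(rec: Recording, profile: SpeciesProfile):
    """Full cleaning pass: channel selection + artifact masking.

    Returns ``(cleaned_recording, include, reasons, mask)``.
    """
    include, reasons, _ = select_channels(rec, profile)
    mask = detect_amplitude_artifacts(rec)
    # scratch/HVS detection runs on the amplitude-cleaned signal so that
    # transients do not pollute the cortical band-power distribution
    if rec.cortical_flag.any():
        mask = mask | remove_scratch_hvs(apply_mask(rec, mask), profile)
    return apply_mask(rec, mask), include, reasons, mask


# ---------------------------------------------------------------------------
# Head tracking


def clean_tracking(raw: TrackingData, max_jump_px: float = 50.0,
                   sep_band_px: Tuple[float, float] = (30.0, 50.0),
                   max_gap_s: float = 0.66, median_width: int = 5) -> TrackingData:
    """De-glitch LED tracking: reflections, gap filling, median smoothing.

    A frame is invalidated if either LED moves more than ``max_jump_px``
    per frame from the last valid position, or the LED separation falls
    outside ``sep_band_px``. Invalid gaps shorter than ``max_gap_s`` are
    linearly interpolated; longer gaps stay invalid. Each coordinate is
    finally median filtered (width 5).
    """
    if raw.n_frames < 2:
        raise ValueError("need at least two frames")
    red, green = raw.red.copy(), raw.green.copy()
    valid = raw.valid.copy()
    sep = np.linalg.norm(red - green, axis=1)
    valid &= (sep >= sep_band_px[0]) & (sep <= sep_band_px[1])

    for led in (red, green):
        last = None
        for i in range(raw.n_frames):
            if not valid[i]:
                continue
            if last is not None:
                j, pos = last
                if np.linalg.norm(led[i] - pos) > max_jump_px * (i - j):
                    valid[i] = False
                    continue
            last = (i, led[i])

    max_gap = int(np.floor(max_gap_s * raw.fps))
    frames = np.arange(raw.n_frames)
    filled = valid.copy()
    if valid.any() and not valid.all():
        edges = np.flatnonzero(np.diff(np.concatenate(([True], valid, [True])) * 1))
        for i0, i1 in edges.reshape(-1, 2):
            if i1 - i0 < max_gap and i0 > 0 and i1 < raw.n_frames:
                for led in (red, green):
                    for k in range(2):
                        led[i0:i1, k] = np.interp(frames[i0:i1], [i0 - 1, i1], [led[i0 - 1, k], led[i1, k]])
                filled[i0:i1] = True

    for led in (red, green):
        for k in range(2):
            led[:, k] = ndimage.median_filter(led[:, k], size=median_width, mode="nearest")
        led[~filled] = np.nan
    return TrackingData(red=red, green=green, fps=raw.fps, valid=filled)


def compute_speed(tracking: TrackingData, px_per_cm: float,
                  out_fs: Optional[float] = None, n_samples: Optional[int] = None) -> SpeedTrace:
    """Head speed (cm/s) from cleaned tracking.

    Head position is the mean of the two LED positions; speed is the
    per-frame displacement scaled by fps / px_per_cm. Invalid frames
    propagate as NaN. Optionally resampled onto the LFP time base.
    """
    if px_per_cm is None or not px_per_cm > 0:
        raise ValueError("px_per_cm must be a positive number (set it in session metadata)")
    head = 0.5 * (tracking.red + tracking.green)
    disp = np.linalg.norm(np.diff(head, axis=0), axis=1)
    v = np.empty(tracking.n_frames)
    v[1:] = disp * tracking.fps / px_per_cm
    v[0] = v[1] if tracking.n_frames > 1 else 0.0
    bad = ~tracking.valid
    v[bad] = np.nan
    v[1:][bad[:-1]] = np.nan
    trace = SpeedTrace(v, tracking.fps)
    if out_fs is not None:
        if n_samples is None:
            n_samples = int(round(trace.duration * out_fs))
        trace = trace.resampled(out_fs, n_samples)
    return trace
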