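"""Autocorrelogram matched-sinusoid statistic ("peak range").

The oscillation statistic at the heart of the pipeline: the LFP is
high-pass + notch pre-filtered, cut into non-overlapping 1 s epochs,
and each epoch's autocorrelogram is compared (normalised Euclidean
distance) to a bank of autocorrelograms of 1 s sinusoids on a 0.1 Hz
grid. The best-matching sinusoid gives the epoch's frequency estimate;
the range of the first autocorrelogram peak (peak maximum minus the
mean of its two flanking troughs), normalised by the same measurement
on the matched sinusoid, gives a dimensionless regularity index that
approaches 1 for periodic signals and 0 for spectrally flat noise.

Because the epoch and the bank use the same biased (divide-by-N)
estimator on the same lag grid, the triangular taper of the biased
autocorrelation cancels in the normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sig

from .filters import iir_prefilter
from .profiles import SpeciesProfile
from .session import Session, SpeedTrace

__all__ = [
    "Autocorrelogram", "SineBank", "EpochRecord",
    "prefilter_for_acg", "epoch_signal", "autocorrelogram",
    "match_sine", "peak_range", "epoch_pipeline",
]

EPOCH_LEN_S = 1.0


@dataclass
class Autocorrelogram:
    """Normalised autocorrelation on a lag grid 0..max_lag (value(0) = 1)."""

    lags: np.ndarray    # seconds
    values: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.values[0], 1.0):
            raise ValueError("autocorrelogram must be normalised to 1 at lag 0")


@dataclass
class EpochRecord:
    """One 1 s analysis epoch of one channel."""

    start: float
    channel: int
    mean_speed: float
    state: str              # immobile | intermediate | moving
    peak_range: float
    est_frequency: float
    trial_epoch: str = "none"
    valid: bool = True


def prefilter_for_acg(x: np.ndarray, profile: SpeciesProfile, fs: float) -> np.ndarray:
    """Species high-pass + 50 Hz notch, forward-backward (zero phase)."""
    return iir_prefilter(np.asarray(x, dtype=float), profile, fs)


def epoch_signal(trace: np.ndarray, speed: Optional[SpeedTrace], fs: float,
                 epoch_len: float = EPOCH_LEN_S):
    """Cut a trace into non-overlapping half-open epochs [t, t+epoch_len).

    Yields ``(start_s, samples, mean_speed, valid)``; an epoch is invalid
    if it contains any masked (non-finite) sample. Mean speed is NaN when
    no speed trace is supplied.
    """
    n_per = int(round(epoch_len * fs))
    trace = np.asarray(trace, dtype=float)
    v = None
    if speed is not None:
        v = speed.values if (speed.fs == fs and speed.values.size >= trace.size) \
            else speed.resampled(fs, trace.size).values
    out = []
    for i0 in range(0, trace.size - n_per + 1, n_per):
        seg = trace[i0:i0 + n_per]
        valid = bool(np.all(np.isfinite(seg)))
        if v is not None:
            window = v[i0:i0 + n_per]
            mean_speed = float(np.mean(window)) if np.all(np.isfinite(window)) else np.nan
        else:
            mean_speed = np.nan
        out.append((i0 / fs, seg, mean_speed, valid))
    return out


def autocorrelogram(x: np.ndarray, max_lag: Optional[int] = None,
                    fs: float = 1.0) -> Autocorrelogram:
    """Biased (divide-by-N) autocorrelation, normalised at lag 0.

    Computed with an FFT cross-correlation; equivalent to the direct
    time-domain sum ``r[k] = (1/N) sum_n x[n] x[n+k]``. Lags are in
    seconds when ``fs`` is given, samples otherwise.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = n - 1
    r = sig.fftconvolve(x, x[::-1], mode="full")[n - 1: n + max_lag]
    if r[0] <= 0:
        raise ValueError("zero-variance epoch; autocorrelogram undefined")
    return Autocorrelogram(lags=np.arange(max_lag + 1) / fs, values=r / r[0])


@dataclass
class SineBank:
    """Reference autocorrelograms of 1 s sinusoids on a frequency grid."""

    frequencies: np.ndarray
    acgs: np.ndarray      # (n_freq, n_lags)
    fs: float

    @classmethod
    def build(cls, profile_or_grid, fs: float, epoch_len: float = EPOCH_LEN_S) -> "SineBank":
        grid = profile_or_grid.sine_grid if isinstance(profile_or_grid, SpeciesProfile) else profile_or_grid
        lo, hi, step = grid
        freqs = np.round(np.arange(lo, hi + step / 2, step), 6)
        n = int(round(epoch_len * fs))
        t = np.arange(n) / fs
        acgs = np.empty((freqs.size, n))
        for i, f in enumerate(freqs):
            acgs[i] = autocorrelogram(np.sin(2 * np.pi * f * t)).values
        return cls(frequencies=freqs, acgs=acgs, fs=fs)


def match_sine(acg: Autocorrelogram, bank: SineBank) -> Tuple[float, np.ndarray]:
    """Best-matching bank sinusoid by normalised Euclidean distance.

    The distance to each reference is divided by the Euclidean norm of
    that reference autocorrelogram; ties break toward the lower
    frequency.
    """
    if acg.values.size != bank.acgs.shape[1]:
        raise ValueError("autocorrelogram and bank use different lag grids")
    diffs = bank.acgs - acg.values[None, :]
    dist = np.linalg.norm(diffs, axis=1) / np.linalg.norm(bank.acgs, axis=1)
    k = int(np.argmin(dist))
    return float(bank.frequencies[k]), bank.acgs[k]


def _first_peak_lags(ref: np.ndarray) -> Optional[Tuple[int, int, int]]:
    """Lags (samples) of the first trough, first peak and second trough
    of a reference autocorrelogram."""
    d = np.diff(ref)
    rising = d > 0
    minima = np.flatnonzero(~rising[:-1] & rising[1:]) + 1
    maxima = np.flatnonzero(rising[:-1] & ~rising[1:]) + 1
    if minima.size == 0 or maxima.size == 0:
        return None
    t1 = minima[0]
    peaks_after = maxima[maxima > t1]
    if peaks_after.size == 0:
        return None
    p = peaks_after[0]
    troughs_after = minima[minima > p]
    if troughs_after.size == 0:
        return None
    return int(t1), int(p), int(troughs_after[0])


def peak_range(acg: Autocorrelogram, matched_ref: np.ndarray, matched_freq: float,
               fs: float) -> float:
    """Normalised range of the first autocorrelogram peak.

    The first peak and its flanking troughs are located on the *matched
    sinusoid's* autocorrelogram; the data extremum is then measured
    within +-1/4 period of each reference lag. The raw range (peak value
    minus the mean of the two trough values) is divided by the
    identically measured range of the reference. Returns NaN when the
    search window leaves the lag grid. The value is not clipped.
    """
    lags = _first_peak_lags(matched_ref)
    if lags is None:
        return np.nan
    t1, p, t2 = lags
    quarter = int(round(fs / (4.0 * matched_freq)))
    n = acg.values.size
    if t2 + quarter >= n:
        return np.nan

    def measure(vals: np.ndarray) -> float:
        lo1, hi1 = max(0, t1 - quarter), t1 + quarter + 1
        lo2, hi2 = max(0, t2 - quarter), t2 + quarter + 1
        lop, hip = max(0, p - quarter), p + quarter + 1
        peak_v = float(np.max(vals[lop:hip]))
        trough_v = 0.5 * (float(np.min(vals[lo1:hi1])) + float(np.min(vals[lo2:hi2])))
        return peak_v - trough_v

    ref_range = measure(matched_ref)
    if ref_range <= 0:
        return np.nan
    return measure(acg.values) / ref_range


def classify_state(mean_speed: float, profile: SpeciesProfile) -> str:
    if not np.isfinite(mean_speed):
        return "intermediate"
    if mean_speed < profile.immobile_threshold:
        return "immobile"
    if mean_speed > profile.moving_epoch_threshold:
        return "moving"
    return "intermediate"


def epoch_pipeline(session: Session, channel: int,
                   profile: Optional[SpeciesProfile] = None,
                   bank: Optional[SineBank] = None) -> List[EpochRecord]:
    """Prefilter -> epoch -> autocorrelogram -> match -> peak range.

    One record per epoch; epochs containing masked samples, or whose
    peak-range window leaves the lag grid, are flagged invalid with NaN
    statistics.
    """
    profile = profile or session.species_profile
    fs = session.recording.fs
    if bank is None:
        bank = SineBank.build(profile, fs)
    trace = prefilter_for_acg(session.recording.samples[channel], profile, fs)
    records: List[EpochRecord] = []
    for start, seg, mean_speed, valid in epoch_signal(trace, session.speed, fs):
        state = classify_state(mean_speed, profile)
        if not valid:
            records.append(EpochRecord(start, channel, mean_speed, state,
                                       np.nan, np.nan, valid=False))
            continue
        acg = autocorrelogram(seg - seg.mean(), fs=fs)
        freq, ref = match_sine(acg, bank)
        pr = peak_range(acg, ref, freq, fs)
        records.append(EpochRecord(start, channel, mean_speed, state, pr, freq,
                                   valid=bool(np.isfinite(pr))))
    return records
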