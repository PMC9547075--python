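"""Filter design helpers shared across pipeline stages.

Zero-lag FIR band-passes (Hamming-windowed sinc, even order so the group
delay is an integer) and the Chebyshev type II IIR cascade (high-pass +
mains notch) applied forward-backward before autocorrelation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .profiles import Cheby2HighpassSpec, NotchSpec, SpeciesProfile

__all__ = ["design_fir_bandpass", "zero_lag_fir", "cheby2_highpass_sos", "notch_sos", "iir_prefilter"]


def design_fir_bandpass(band, order_s: float, fs: float) -> np.ndarray:
    """Hamming-windowed sinc band-pass; order = round(order_s * fs), forced even."""
    order = int(round(order_s * fs))
    if order % 2:
        order += 1
    return signal.firwin(order + 1, band, pass_zero=False, window="hamming", fs=fs)


def zero_lag_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with group-delay compensation.

    NaN (masked) input samples are zero-filled before convolution and any
    output sample whose filter support touched a masked or out-of-range
    sample is set to NaN, so extrema are never detected across a mask
    boundary or inside the edge transients.
    """
    half = (len(taps) - 1) // 2
    nan_in = ~np.isfinite(x)
    x0 = np.where(nan_in, 0.0, x)
    y = signal.fftconvolve(x0, taps, mode="same")
    if nan_in.any():
        touched = signal.fftconvolve(nan_in.astype(float), np.ones(len(taps)), mode="same") > 0.5
        y[touched] = np.nan
    if half > 0:
        y[:half] = np.nan
        y[-half:] = np.nan
    return y


def cheby2_highpass_sos(spec: Cheby2HighpassSpec, fs: float) -> np.ndarray:
    """Chebyshev-II high-pass with a prescribed order and *passband* edge.

    scipy's ``cheby2`` is parameterised by the stopband edge; the stopband
    corner is located by bisection so the magnitude response crosses -3 dB
    at the requested passband edge frequency.
    """
    target = spec.passband_edge_hz

    def atten_at_passband(ws: float) -> float:
        sos = signal.cheby2(spec.order, spec.stopband_atten_db, ws, "highpass", fs=fs, output="sos")
        w, h = signal.sosfreqz(sos, worN=[target], fs=fs)
        return 20.0 * np.log10(np.abs(h[0]) + 1e-300)

    lo, hi = 1e-3, target * 0.999
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if atten_at_passband(mid) > -3.0:
            lo = mid
        else:
            hi = mid
    return signal.cheby2(spec.order, spec.stopband_atten_db, lo, "highpass", fs=fs, output="sos")


def notch_sos(spec: NotchSpec, fs: float) -> np.ndarray:
    """Band-stop Chebyshev II; a section order of n/2 gives an n-th order band-stop."""
    return signal.cheby2(spec.order // 2, spec.stopband_atten_db, list(spec.stopband_hz),
                         "bandstop", fs=fs, output="sos")


def iir_prefilter(x: np.ndarray, profile: SpeciesProfile, fs: float) -> np.ndarray:
    """High-pass + 50 Hz notch, executed forward-backward (zero phase).

    NaN runs split the trace; each finite segment longer than the filter
    padding is filtered independently, shorter ones stay NaN.
    """
    sos = np.vstack([cheby2_highpass_sos(profile.hp_filter, fs), notch_sos(profile.notch_spec, fs)])
    pad = 3 * (sos.shape[0] * 2 + 1)
    y = np.full_like(x, np.nan, dtype=float)
    finite = np.isfinite(x)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], finite, [False]))))
    for i0, i1 in edges.reshape(-1, 2):
        if i1 - i0 > pad:
            y[i0:i1] = signal.sosfiltfilt(sos, x[i0:i1])
    return y
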