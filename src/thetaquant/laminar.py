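"""Laminar depth profiles and hippocampal layer assignment.

Theta power rises and its phase reverses (~180 deg) travelling through
the pyramidal cell layer on a linear probe; the pipeline exploits this
to locate the stratum pyramidale (SP: power dip at the onset of the
phase shift), from which the stratum oriens (SO, 200 um above) and the
stratum radiatum / lacunosum-moleculare (SR/SLM, 400 um below) are
assigned. Probes that never cross the cell layer fall back to the
highest-theta-power channel as SO. Per-channel speed-theta regressions
(frequency and power) complete the depth profile, with Bonferroni
correction across channels; a ripple-band power profile is available as
an independent confirmation aid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sig
from scipy import stats

from .profiles import SpeciesProfile
from .session import Recording, Session, SpeedTrace
from .stats import bonferroni_alpha
from .theta import ThetaInstantaneous, theta_for_channel

__all__ = ["DepthProfile", "LayerMap", "RegressionResult", "theta_depth_profile",
           "speed_theta_regression", "estimate_layers", "ripple_power_profile"]

log = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """OLS fit on speed-bin medians of a 250 ms epoch statistic."""

    beta0: float
    beta1: float
    p: float
    r2: float
    n_bins: int
    bin_edges: np.ndarray
    significant: bool = False


@dataclass
class DepthProfile:
    """Per-channel theta statistics along the probe."""

    channels: np.ndarray
    depth_um: np.ndarray
    power_median: np.ndarray
    power_iqr: np.ndarray          # (2, n_channels): 25th/75th percentiles
    phase_mean_deg: np.ndarray     # circular mean re top channel (0 for top)
    phase_sd_deg: np.ndarray
    slope_freq: np.ndarray
    slope_power: np.ndarray
    sig_freq: np.ndarray
    sig_power: np.ndarray


@dataclass
class LayerMap:
    """Channel indices of the identified hippocampal layers."""

    sp_channel: Optional[int]
    so_channel: Optional[int]
    srslm_channel: Optional[int]
    method: str                    # "profile" | "power-peak fallback"


def _epoch_medians(values: np.ndarray, speed: np.ndarray, fs: float,
                   epoch_s: float = 0.25) -> Tuple[np.ndarray, np.ndarray]:
    n_per = int(round(epoch_s * fs))
    n_ep = values.size // n_per
    v = values[: n_ep * n_per].reshape(n_ep, n_per)
    s = speed[: n_ep * n_per].reshape(n_ep, n_per)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN epochs are dropped later
        return np.nanmedian(v, axis=1), np.nanmedian(s, axis=1)


def speed_theta_regression(inst: ThetaInstantaneous, speed: SpeedTrace,
                           target: str = "frequency", move_threshold: float = 10.0,
                           bin_width: float = 5.0, alpha: float = bonferroni_alpha(32),
                           min_epochs: int = 100) -> Optional[RegressionResult]:
    """Regress a theta statistic on locomotion speed.

    250 ms epoch medians of speed and the target statistic are formed;
    epochs slower than ``move_threshold`` (median speed) or above the
    90th speed percentile are excluded; the remainder are binned at
    ``bin_width`` cm/s and an ordinary least-squares line is fitted to
    the bin medians. ``p`` comes from the slope t-test and the
    significance flag applies the (Bonferroni-corrected) ``alpha``.
    """
    if target not in ("frequency", "power"):
        raise ValueError("target must be 'frequency' or 'power'")
    values = getattr(inst, target)
    v = speed.values if speed.fs == inst.fs else speed.resampled(inst.fs, values.size).values
    med_y, med_s = _epoch_medians(values, v[: values.size], inst.fs)
    keep = np.isfinite(med_y) & np.isfinite(med_s) & (med_s >= move_threshold)
    med_y, med_s = med_y[keep], med_s[keep]
    if med_s.size < min_epochs:
        log.warning("only %d usable locomotion epochs; regression undefined", med_s.size)
        return None
    p90 = np.percentile(med_s, 90)
    keep = med_s <= p90
    med_y, med_s = med_y[keep], med_s[keep]
    edges = np.arange(move_threshold, med_s.max() + bin_width, bin_width)
    bin_s, bin_y = [], []
    min_per_bin = 10  # sparse bins carry unstable medians and inflate the slope test
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (med_s >= lo) & (med_s < hi)
        if sel.sum() >= min_per_bin:
            bin_s.append(np.median(med_s[sel]))
            bin_y.append(np.median(med_y[sel]))
    if len(bin_s) < 3:
        log.warning("fewer than 3 usable speed bins; regression undefined")
        return None
    fit = stats.linregress(bin_s, bin_y)
    return RegressionResult(beta0=float(fit.intercept), beta1=float(fit.slope),
                            p=float(fit.pvalue), r2=float(fit.rvalue ** 2),
                            n_bins=len(bin_s), bin_edges=edges,
                            significant=bool(fit.pvalue < alpha))


def _circular_mean_sd_deg(x_deg: np.ndarray) -> Tuple[float, float]:
    rad = np.deg2rad(x_deg[np.isfinite(x_deg)])
    if rad.size == 0:
        return np.nan, np.nan
    mean = stats.circmean(rad, high=np.pi, low=-np.pi)
    sd = stats.circstd(rad, high=np.pi, low=-np.pi)
    return float(np.rad2deg(mean)), float(np.rad2deg(sd))


def theta_depth_profile(session: Session, profile: Optional[SpeciesProfile] = None,
                        channels: Optional[Sequence[int]] = None,
                        min_locomotion_s: float = 60.0,
                        with_regressions: bool = True) -> DepthProfile:
    """Depth profile of theta power, phase shift and speed coupling.

    Peak-trough theta estimates are computed per channel and restricted
    to locomotion samples (speed above the profile's move threshold);
    phase offsets are circular means relative to the top analysed
    channel, which is 0 by definition.
    """
    profile = profile or session.species_profile
    rec = session.recording
    if session.speed is None:
        raise ValueError("depth profile requires a speed trace")
    v = session.speed.resampled(rec.fs, rec.n_samples).values
    moving = np.isfinite(v) & (v > profile.move_threshold)
    if moving.sum() / rec.fs < min_locomotion_s:
        raise ValueError(f"need >= {min_locomotion_s:.0f} s of locomotion data")
    channels = np.asarray(channels if channels is not None else np.arange(rec.n_channels))
    alpha = bonferroni_alpha(len(channels))
    insts: List[ThetaInstantaneous] = []
    for c in channels:
        insts.append(theta_for_channel(rec.samples[c], profile, rec.fs))

    n_ch = len(channels)
    power_median = np.full(n_ch, np.nan)
    power_iqr = np.full((2, n_ch), np.nan)
    phase_mean = np.zeros(n_ch)
    phase_sd = np.zeros(n_ch)
    slope_f = np.full(n_ch, np.nan)
    slope_p = np.full(n_ch, np.nan)
    sig_f = np.zeros(n_ch, dtype=bool)
    sig_p = np.zeros(n_ch, dtype=bool)
    top = insts[0]
    speed_trace = SpeedTrace(v, rec.fs)
    for i, inst in enumerate(insts):
        pw = inst.power[moving]
        pw = pw[np.isfinite(pw)]
        if pw.size:
            power_median[i] = np.median(pw)
            power_iqr[:, i] = np.percentile(pw, [25, 75])
        diff = inst.phase[moving] - top.phase[moving]
        diff = np.mod(diff + 180.0, 360.0) - 180.0
        phase_mean[i], phase_sd[i] = _circular_mean_sd_deg(diff)
        if with_regressions:
            for target, slopes, sigs in (("frequency", slope_f, sig_f), ("power", slope_p, sig_p)):
                res = speed_theta_regression(inst, speed_trace, target,
                                             move_threshold=profile.move_threshold, alpha=alpha)
                if res is not None:
                    slopes[i] = res.beta1
                    sigs[i] = res.significant
    phase_mean[0] = 0.0  # top channel defines the reference
    return DepthProfile(channels=channels, depth_um=rec.channel_depth[channels],
                        power_median=power_median, power_iqr=power_iqr,
                        phase_mean_deg=phase_mean, phase_sd_deg=phase_sd,
                        slope_freq=slope_f, slope_power=slope_p,
                        sig_freq=sig_f, sig_power=sig_p)


def estimate_layers(profile: DepthProfile, channel_spacing_um: float = 100.0,
                    phase_gradient_deg: float = 20.0, sustain: int = 2) -> LayerMap:
    """Assign SP/SO/SR-SLM channels from a depth profile.

    SP is the channel minimising theta power within the zone where the
    unwrapped phase-shift gradient first exceeds ``phase_gradient_deg``
    per channel sustained over ``sustain`` channels. SO and SR/SLM are
    taken 200 um above and 400 um below via the depth field. Probes with
    no co-occurring dip and phase shift fall back to the highest-power
    channel as SO.
    """
    if len(profile.channels) < 8:
        raise ValueError("need a profile over at least 8 contiguous channels")
    phase = np.deg2rad(profile.phase_mean_deg)
    unwrapped = np.rad2deg(np.unwrap(phase))
    grad = np.abs(np.diff(unwrapped))
    onset = None
    for i in range(len(grad) - sustain + 1):
        if np.all(grad[i:i + sustain] > phase_gradient_deg):
            onset = i
            break
    if onset is None:
        k = int(np.nanargmax(profile.power_median))
        log.warning("no sustained phase shift found; power-peak fallback for SO")
        return LayerMap(sp_channel=None, so_channel=int(profile.channels[k]),
                        srslm_channel=None, method="power-peak fallback")
    lo, hi = max(0, onset - 1), min(len(profile.channels), onset + 2)
    zone = slice(lo, hi)
    k = lo + int(np.nanargmin(profile.power_median[zone]))
    sp = int(profile.channels[k])
    so_shift = int(round(200.0 / channel_spacing_um))
    sr_shift = int(round(400.0 / channel_spacing_um))
    so = sp - so_shift if k - so_shift >= 0 else None
    srslm = sp + sr_shift if k + sr_shift < len(profile.channels) else None
    return LayerMap(sp_channel=sp, so_channel=so, srslm_channel=srslm, method="profile")


def ripple_power_profile(rec: Recording, band: Tuple[float, float] = (150.0, 250.0)) -> np.ndarray:
    """Per-channel RMS power in the ripple band (confirmation aid only)."""
    lo, hi = band
    if lo >= hi:
        raise ValueError("ripple band must satisfy lo < hi")
    if rec.fs < 2.0 * hi:
        raise ValueError("sampling rate too low for the ripple band")
    sos = sig.butter(4, [lo, hi], "bandpass", fs=rec.fs, output="sos")
    out = np.empty(rec.n_channels)
    for c in range(rec.n_channels):
        x = rec.samples[c]
        x = np.where(np.isfinite(x), x, 0.0)
        filt = sig.sosfiltfilt(sos, x)
        out[c] = np.sqrt(np.mean(filt ** 2))
    return out
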