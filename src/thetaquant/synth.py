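"""Synthetic laminar LFP + locomotion generator.

Forward model producing :class:`~thetaquant.session.Session` objects with
the statistical structure the analysis pipeline assumes:

* a trial-structured head-speed trace (Hold / Run / Reward / inter-trial
  wandering) with realistic running speeds;
* speed-coupled theta with a skewed ("sawtooth-like") waveform, a laminar
  amplitude/phase profile across the probe (power dip and ~180 deg phase
  reversal through the pyramidal cell layer), and broadband 1/f "large
  irregular activity" (LIA) on every channel;
* species-specific state rules — rat: theta only during locomotion,
  replaced by LIA when still; ferret: theta in both states, ~1 Hz slower
  and more sinusoidal when immobile, enhanced below the cell layer during
  Reward; atropine mode: immobility theta abolished, locomotion theta
  untouched;
* injected artifacts (broadband transients, 8-12 Hz "scratching" bursts
  strongest on cortical channels, runs of zeros and rail saturation) with
  a ground-truth mask.

The generator is purely phenomenological — it emulates the *signal
statistics* the analysis keys on, not hippocampal biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .profiles import get_profile
from .session import Recording, Session, SpeedTrace, TrackingData, TrialRecord

__all__ = [
    "ArtifactSpec",
    "TrialSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate_speed_trace",
    "generate_lfp",
    "inject_artifacts",
    "generate_session",
    "synthesize_tracking",
]


@dataclass
class ArtifactSpec:
    """Rates (events per second) and magnitudes of injected artifacts."""

    transient_rate: float = 0.0
    transient_amp_factor: float = 20.0   # x median absolute amplitude
    transient_dur_s: float = 0.1
    scratch_rate: float = 0.0
    scratch_dur_s: float = 1.0
    scratch_amp_cortical_uv: float = 300.0
    scratch_amp_hippocampal_uv: float = 40.0
    zero_rate: float = 0.0
    zero_dur_s: float = 0.5
    saturation_rate: float = 0.0
    saturation_dur_s: float = 0.2
    saturation_rail_uv: float = 2000.0


@dataclass
class TrialSpec:
    """Behavioural trial timing of the approach-to-target task."""

    hold_choices_s: Tuple[float, ...] = (2.5, 2.75, 3.0, 3.25, 3.5)
    reaction_s: float = 0.3
    run_ramp_s: float = 0.4
    run_plateau_range: Tuple[float, float] = (25.0, 32.0)
    run_plateau_dur_range: Tuple[float, float] = (1.0, 2.0)
    run_decel_s: float = 0.3
    reward_dwell_range: Tuple[float, float] = (2.0, 3.0)
    intertrial_range: Tuple[float, float] = (2.0, 5.0)
    p_correct: float = 0.8
    n_choices: int = 5


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic session generator.

    Use :meth:`default` for species defaults; the laminar amplitude and
    phase profiles are derived from ``sp_channel`` unless given
    explicitly. The seed fully determines the output.
    """

    species_mode: str = "rat"
    drug_mode: str = "none"              # "none" | "atropine"
    n_channels: int = 32
    channel_spacing_um: float = 100.0
    fs: float = 1000.0
    duration_s: float = 300.0
    theta_base_freq: float = 7.5         # Hz at speed 0, theta-on
    speed_freq_slope: float = 0.026      # Hz per cm/s
    immobility_freq_offset: float = 1.0  # Hz reduction when immobile (ferret)
    sp_channel: int = 18                 # pyramidal-layer channel of the profile
    n_cortical: Optional[int] = None     # default: 10 for rat, 0 for ferret
    theta_amp_profile: Optional[np.ndarray] = None   # per-channel uV
    phase_shift_profile: Optional[np.ndarray] = None # per-channel deg
    sawtooth_skew: float = 0.3           # 0 = sinusoid
    lia_exponent: float = 1.5            # 1/f^alpha
    lia_amp: float = 30.0                # uV RMS
    reward_gain_srslm: float = 1.3
    speed_jitter_sd: float = 1.0         # cm/s, clipped at +-3 SD and at 0
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    trial_spec: TrialSpec = field(default_factory=TrialSpec)
    seed: int = 0

    @classmethod
    def default(cls, species: str = "rat", drug: str = "none", **overrides) -> "GeneratorConfig":
        """Species defaults for the generator's theta parameters.

        Rat: 7.5 Hz base, slope 0.026 Hz/(cm/s); ferret: 5.2 Hz base,
        slope 0.010, 1 Hz slower when immobile. These are generator
        conventions chosen to land in the observed cross-species ranges,
        not claims about the animals.
        """
        params = dict(species_mode=species, drug_mode=drug)
        if species == "ferret":
            params.update(theta_base_freq=5.2, speed_freq_slope=0.010,
                          immobility_freq_offset=1.0)
        elif species != "rat":
            raise ValueError(f"unknown species_mode {species!r}")
        params.update(overrides)
        return cls(**params)

    def __post_init__(self):
        if self.drug_mode not in ("none", "atropine"):
            raise ValueError("drug_mode must be 'none' or 'atropine'")
        if self.n_cortical is None:
            self.n_cortical = 10 if self.species_mode == "rat" else 0
        if self.n_cortical >= self.sp_channel:
            raise ValueError("cortical zone must end above the pyramidal layer channel")
        if self.theta_amp_profile is None:
            self.theta_amp_profile = self._default_amp_profile()
        self.theta_amp_profile = np.asarray(self.theta_amp_profile, dtype=float)
        if self.phase_shift_profile is None:
            self.phase_shift_profile = self._default_phase_profile()
        self.phase_shift_profile = np.asarray(self.phase_shift_profile, dtype=float)
        for prof in (self.theta_amp_profile, self.phase_shift_profile):
            if prof.shape != (self.n_channels,):
                raise ValueError("laminar profiles must have one entry per channel")
        if np.any(self.theta_amp_profile < 0):
            raise ValueError("theta amplitudes must be non-negative")
        min_trial = min(self.trial_spec.hold_choices_s) + 3.0
        if self.duration_s < min_trial:
            raise ValueError("duration_s too short for a single trial")

    def _default_amp_profile(self) -> np.ndarray:
        """Laminar theta amplitude (uV): low in cortex, moderate in SO,
        dip at SP, high below (SR/SLM)."""
        amp = np.full(self.n_channels, 55.0)
        amp[: self.n_cortical] = 4.0
        sp = self.sp_channel
        amp[sp] = 22.0
        if sp - 1 >= self.n_cortical:
            amp[sp - 1] = 40.0
        if sp + 1 < self.n_channels:
            amp[sp + 1] = 60.0
        for i, a in zip(range(sp + 2, self.n_channels), (85.0, 110.0)):
            amp[i] = a
        amp[sp + 4:] = 110.0
        return amp

    def _default_phase_profile(self) -> np.ndarray:
        """Phase offset (deg): 0 above SP, ramping to 180 across the
        three channels below the cell layer."""
        phase = np.zeros(self.n_channels)
        sp = self.sp_channel
        ramp = np.linspace(0.0, 180.0, 4)[1:]  # 60, 120, 180
        for i, p in zip(range(sp + 1, self.n_channels), ramp):
            phase[i] = p
        phase[sp + 4:] = 180.0
        return phase

    @property
    def srslm_channels(self) -> np.ndarray:
        """Channels treated as SR/SLM by the generator (>= SP + 400 um)."""
        shift = int(round(400.0 / self.channel_spacing_um))
        return np.arange(min(self.sp_channel + shift, self.n_channels), self.n_channels)

    def to_meta(self) -> dict:
        d = asdict(self)
        d["theta_amp_profile"] = [float(v) for v in self.theta_amp_profile]
        d["phase_shift_profile"] = [float(v) for v in self.phase_shift_profile]
        return d


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must estimate."""

    speed_clean: np.ndarray            # cm/s, pre-jitter, per sample
    theta_on: np.ndarray               # bool per sample
    true_freq: np.ndarray              # Hz per sample (NaN when theta off)
    amp_profile: np.ndarray            # per-channel uV
    envelope_gain: np.ndarray          # per-sample multiplicative gain (reward etc.)
    sp_channel: int
    so_channel: int
    srslm_channel: Optional[int]
    artifact_mask: Optional[np.ndarray] = None       # bool per sample (all channels)
    artifact_labels: Dict[str, np.ndarray] = field(default_factory=dict)
    trial_windows: List[Tuple[int, str, float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Speed / behaviour


def generate_speed_trace(cfg: GeneratorConfig):
    """Simulate the head-speed trace and trial table.

    Returns ``(speed, trials, truth_windows, speed_clean)`` where
    ``speed`` carries additive jitter (SD ``speed_jitter_sd``, clipped at
    +-3 SD and at zero) and ``truth_windows`` holds the ground-truth
    Hold/Run/Reward windows (1 s each) per trial.
    """
    rng = np.random.default_rng(cfg.seed)
    ts = cfg.trial_spec
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    speed = np.zeros(n)
    trials: List[TrialRecord] = []
    windows: List[Tuple[int, str, float, float]] = []

    def fill(t0: float, t1: float, values) -> None:
        i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n)
        if i1 > i0:
            speed[i0:i1] = values if np.isscalar(values) else values[: i1 - i0]

    t = 0.0
    trial_idx = 0
    while True:
        # inter-trial wandering: mean-reverting meander over 0-25 cm/s so
        # moderate speeds are sampled in quasi-steady state, as they are when
        # animals explore between trials
        wander = rng.uniform(*ts.intertrial_range)
        base = rng.uniform(2.0, 22.0)
        i0, i1 = int(round(t * fs)), min(int(round((t + wander) * fs)), n)
        if i1 > i0:
            m = i1 - i0
            x = np.empty(m)
            x[0] = base
            tau, sigma, dt = 1.0, 3.0, 1.0 / fs
            noise = rng.normal(0.0, sigma * np.sqrt(dt), m)
            for k in range(1, m):
                x[k] = x[k - 1] + (base - x[k - 1]) * dt / tau + noise[k]
            speed[i0:i1] = np.clip(x, 0.0, 25.0)
        t += wander

        hold = float(rng.choice(ts.hold_choices_s))
        plateau = rng.uniform(*ts.run_plateau_range)
        plateau_dur = rng.uniform(*ts.run_plateau_dur_range)
        reward_dwell = rng.uniform(*ts.reward_dwell_range)
        run_dur = ts.run_ramp_s + plateau_dur + ts.run_decel_s
        t_end = t + hold + ts.reaction_s + run_dur + reward_dwell
        if t_end > cfg.duration_s:
            break
        hold_start = t
        fill(t, t + hold, rng.uniform(0.5, 1.5))
        t += hold
        onset = t
        fill(t, t + ts.reaction_s, 1.0)
        t += ts.reaction_s
        # run: ramp - plateau - decelerate onto the response spout
        n_ramp = int(round(ts.run_ramp_s * fs))
        fill(t, t + ts.run_ramp_s, np.linspace(2.0, plateau, n_ramp))
        t += ts.run_ramp_s
        fill(t, t + plateau_dur, plateau)
        t += plateau_dur
        n_dec = int(round(ts.run_decel_s * fs))
        fill(t, t + ts.run_decel_s, np.linspace(plateau, 1.0, n_dec))
        t += ts.run_decel_s
        response = t
        fill(t, t + reward_dwell, rng.uniform(0.5, 1.5))
        t += reward_dwell

        correct = bool(rng.random() < ts.p_correct)
        target = int(rng.integers(ts.n_choices))
        if correct:
            resp_loc = target
        else:
            resp_loc = int((target + 1 + rng.integers(ts.n_choices - 1)) % ts.n_choices)
        trials.append(TrialRecord(
            hold_start=hold_start, stimulus_onset=onset,
            modality="A" if rng.random() < 0.5 else "V",
            target_location=target, response_time=response,
            response_location=resp_loc, correct=correct,
        ))
        windows.append((trial_idx, "Hold", onset - 1.05, onset - 0.05))
        windows.append((trial_idx, "Run", response - 1.0, response))
        windows.append((trial_idx, "Reward", response + 0.1, response + 1.1))
        trial_idx += 1

    speed_clean = speed.copy()
    jitter = rng.normal(0.0, cfg.speed_jitter_sd, n)
    np.clip(jitter, -3.0 * cfg.speed_jitter_sd, 3.0 * cfg.speed_jitter_sd, out=jitter)
    speed = np.clip(speed + jitter, 0.0, None)
    return SpeedTrace(speed, fs), trials, windows, speed_clean


# ---------------------------------------------------------------------------
# LFP synthesis


def _skewed_wave(phase: np.ndarray, skew: np.ndarray) -> np.ndarray:
    """Sawtooth-like waveform via asymmetric cycle warping of a sinusoid.

    The rising half of each cycle is compressed to a fraction
    ``r = 0.5 - 0.4 * skew`` of the period (skew 0 -> pure sinusoid),
    which introduces the harmonic content characteristic of locomotor
    theta without changing the fundamental frequency.
    """
    u = np.mod(phase / (2.0 * np.pi), 1.0)
    r = 0.5 - 0.4 * np.asarray(skew)
    rising = u < r
    w = np.where(rising, 0.5 * u / r, 0.5 + 0.5 * (u - r) / (1.0 - r))
    return np.sin(2.0 * np.pi * w)


def _smooth_gate(flag: np.ndarray, fs: float, ramp_s: float = 0.2) -> np.ndarray:
    """0/1 indicator smoothed with a Hann window (soft on/off transitions)."""
    n_win = max(3, int(round(ramp_s * fs)) | 1)
    win = np.hanning(n_win)
    win /= win.sum()
    return np.convolve(flag.astype(float), win, mode="same")


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, rms: float) -> np.ndarray:
    """Gaussian 1/f^alpha noise with the requested RMS amplitude."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    x *= rms / np.std(x)
    return x


def generate_lfp(cfg: GeneratorConfig, speed: SpeedTrace,
                 speed_clean: Optional[np.ndarray] = None,
                 trial_windows: Optional[list] = None):
    """Synthesise the laminar LFP for a given speed trace.

    Per channel c: ``x_c(t) = A_c(t) * skewed_sin(phi(t) + off_c) + LIA_c(t)``
    with instantaneous frequency ``f(t) = base + slope * v(t)`` while theta
    is on. Theta-on rule — rat: only when v(t) exceeds the locomotion
    threshold; ferret: always on, with frequency reduced by the immobility
    offset and skew -> 0 when still; atropine: theta off when immobile in
    either species. SR/SLM channel amplitudes are multiplied by
    ``reward_gain_srslm`` inside Reward windows.
    """
    if speed_clean is None:
        speed_clean = speed.values
    n = int(round(cfg.duration_s * cfg.fs))
    if speed_clean.size < n:
        raise ValueError("speed trace does not cover the requested duration")
    fs = cfg.fs
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    v = speed_clean[:n]
    profile = get_profile(cfg.species_mode)
    moving = v > profile.move_threshold
    move_gate = _smooth_gate(moving, fs)

    if cfg.species_mode == "ferret" and cfg.drug_mode == "none":
        on_gate = np.ones(n)
        freq = (cfg.theta_base_freq - cfg.immobility_freq_offset * (1.0 - move_gate)
                + cfg.speed_freq_slope * v)
        skew = cfg.sawtooth_skew * move_gate  # sinusoidal when immobile
    else:
        # rat, or atropine mode in either species: theta only during locomotion
        on_gate = move_gate
        freq = cfg.theta_base_freq + cfg.speed_freq_slope * v
        skew = np.full(n, cfg.sawtooth_skew)

    phase = 2.0 * np.pi * np.cumsum(freq) / fs

    env_gain = np.ones(n)
    if trial_windows and cfg.reward_gain_srslm != 1.0:
        reward_flag = np.zeros(n, dtype=bool)
        for _, label, t0, t1 in trial_windows:
            if label == "Reward":
                i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n)
                reward_flag[i0:i1] = True
        env_gain += (cfg.reward_gain_srslm - 1.0) * _smooth_gate(reward_flag, fs)

    srslm = set(cfg.srslm_channels.tolist())
    samples = np.empty((cfg.n_channels, n), dtype=np.float32)
    for c in range(cfg.n_channels):
        off = np.deg2rad(cfg.phase_shift_profile[c])
        wave = _skewed_wave(phase + off, skew)
        amp = cfg.theta_amp_profile[c] * on_gate
        if c in srslm:
            amp = amp * env_gain
        samples[c] = amp * wave + _pink_noise(rng, n, cfg.lia_exponent, cfg.lia_amp)

    depth = np.arange(cfg.n_channels) * cfg.channel_spacing_um
    cortical = np.zeros(cfg.n_channels, dtype=bool)
    cortical[: cfg.n_cortical] = True
    rec = Recording(samples=samples, fs=fs, channel_depth=depth, cortical_flag=cortical)

    shift = int(round(400.0 / cfg.channel_spacing_um))
    srslm_ch = cfg.sp_channel + shift if cfg.sp_channel + shift < cfg.n_channels else None
    truth = GroundTruth(
        speed_clean=v,
        theta_on=on_gate > 0.5,
        true_freq=np.where(on_gate > 0.5, freq, np.nan),
        amp_profile=cfg.theta_amp_profile.copy(),
        envelope_gain=env_gain,
        sp_channel=cfg.sp_channel,
        so_channel=cfg.sp_channel - int(round(200.0 / cfg.channel_spacing_um)),
        srslm_channel=srslm_ch,
        trial_windows=list(trial_windows or []),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Artifacts


def inject_artifacts(rec: Recording, cfg: GeneratorConfig, rng=None):
    """Add transients, scratching bursts, zero runs and saturation.

    Returns ``(recording, mask, labels)``: a new Recording with artifacts
    added (valid_mask untouched — masking them is the cleaning module's
    job), the combined per-sample ground-truth mask, and per-category
    masks. All artifact classes hit every channel simultaneously, as
    movement/telemetry artifacts do.
    """
    spec = cfg.artifact_spec
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = rec.n_samples
    fs = rec.fs
    samples = rec.samples.copy()
    labels = {k: np.zeros(n, dtype=bool) for k in ("transient", "scratch", "zero", "saturation")}

    typical = np.median(np.abs(samples))

    def windows(rate: float, dur_s: float):
        count = rng.poisson(rate * n / fs)
        dur = int(round(dur_s * fs))
        out = []
        for _ in range(count):
            i0 = int(rng.integers(0, max(1, n - dur)))
            out.append((i0, min(i0 + dur, n)))
        return out

    for i0, i1 in windows(spec.transient_rate, spec.transient_dur_s):
        amp = spec.transient_amp_factor * typical
        burst = amp * np.sign(rng.standard_normal(i1 - i0)) * rng.uniform(1.0, 1.5, i1 - i0)
        samples[:, i0:i1] += burst.astype(np.float32)
        labels["transient"][i0:i1] = True

    for i0, i1 in windows(spec.scratch_rate, spec.scratch_dur_s):
        f = rng.uniform(8.0, 12.0)
        t = np.arange(i1 - i0) / fs
        tone = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        for c in range(rec.n_channels):
            a = spec.scratch_amp_cortical_uv if rec.cortical_flag[c] else spec.scratch_amp_hippocampal_uv
            samples[c, i0:i1] += (a * tone).astype(np.float32)
        labels["scratch"][i0:i1] = True

    for i0, i1 in windows(spec.zero_rate, spec.zero_dur_s):
        samples[:, i0:i1] = 0.0
        labels["zero"][i0:i1] = True

    for i0, i1 in windows(spec.saturation_rate, spec.saturation_dur_s):
        samples[:, i0:i1] = np.float32(spec.saturation_rail_uv)
        labels["saturation"][i0:i1] = True

    mask = np.zeros(n, dtype=bool)
    for lab in labels.values():
        mask |= lab
    out = Recording(samples=samples, fs=fs, channel_depth=rec.channel_depth.copy(),
                    cortical_flag=rec.cortical_flag.copy())
    return out, mask, labels


# ---------------------------------------------------------------------------
# Tracking synthesis


def synthesize_tracking(speed: SpeedTrace, fps: float, px_per_cm: float,
                        seed: int = 0, led_sep_px: float = 40.0) -> TrackingData:
    """Render a speed trace as red/green LED pixel tracks.

    The head follows a smooth random-walk heading at the prescribed
    speed; the two LEDs sit ``led_sep_px`` apart along the heading, so
    their average is the head position. Inverse of
    :func:`thetaquant.cleaning.compute_speed` up to discretisation.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(np.floor(speed.duration * fps))
    t = np.arange(n_frames) / fps
    v = np.interp(t, speed.times(), np.nan_to_num(speed.values))  # cm/s
    heading = np.cumsum(rng.normal(0, 0.05, n_frames))
    step = v / fps * px_per_cm
    pos = np.cumsum(np.column_stack([step * np.cos(heading), step * np.sin(heading)]), axis=0)
    half = 0.5 * led_sep_px
    offset = np.column_stack([half * np.cos(heading), half * np.sin(heading)])
    return TrackingData(red=pos + offset, green=pos - offset, fps=fps)


# ---------------------------------------------------------------------------
# Composition


def generate_session(cfg: GeneratorConfig, with_tracking: bool = False):
    """Generate a complete, loadable Session plus its ground truth."""
    speed, trials, windows, speed_clean = generate_speed_trace(cfg)
    rec, truth = generate_lfp(cfg, speed, speed_clean, windows)
    rec, art_mask, art_labels = inject_artifacts(rec, cfg)
    truth.artifact_mask = art_mask
    truth.artifact_labels = art_labels
    tracking = None
    if with_tracking:
        fps = 25.0 if cfg.species_mode == "rat" else 30.0
        tracking = synthesize_tracking(speed, fps=fps, px_per_cm=4.0, seed=cfg.seed + 7)
    session = Session(
        recording=rec,
        species_profile=get_profile(cfg.species_mode),
        speed=speed,
        tracking=tracking,
        trials=trials,
        meta={"drug": cfg.drug_mode, "px_per_cm": 4.0, "generator": cfg.to_meta()},
    )
    return session, truth
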