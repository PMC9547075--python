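"""Session container: in-memory domain types and HDF5 persistence.

A :class:`Session` bundles everything the pipeline needs for one
recording session: the multichannel LFP (:class:`Recording`), optional
head tracking and derived speed, the behavioural trial table and the
species profile. Sessions round-trip through a neutral HDF5 layout::

    /lfp            channel x time, float32, microvolts (NaN = masked)
    /fs             scalar, Hz
    /channel_depth  per channel, micrometres
    /cortical_flag  per channel, bool
    /valid_mask     channel x time, bool
    /speed          per sample, cm/s (optional; attr fs)
    /tracking/...   LED positions, px (optional)
    /trials/...     trial table columns (optional)
    /meta           attributes (JSON-encoded values)

Times are seconds from recording start; channels are 0-based and carry
explicit depths; masked samples are NaN with ``valid_mask`` false.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .profiles import SpeciesProfile, get_profile

__all__ = [
    "Recording",
    "SpeedTrace",
    "TrackingData",
    "TrialRecord",
    "Session",
    "SchemaError",
    "save_session",
    "load_session",
    "export_epoch_table",
    "import_epoch_table",
]

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    """Raised when an on-disk container is missing mandatory datasets."""


@dataclass
class Recording:
    """Multichannel LFP matrix in microvolts.

    ``samples`` is channel x time; masked samples are NaN and carry
    ``valid_mask == False``. ``channel_depth`` (um) must be strictly
    increasing (probe contacts ordered from top to tip, typically at
    100 um spacing).
    """

    samples: np.ndarray
    fs: float
    channel_depth: np.ndarray
    cortical_flag: np.ndarray
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty channel x time matrix")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.channel_depth = np.asarray(self.channel_depth, dtype=float)
        self.cortical_flag = np.asarray(self.cortical_flag, dtype=bool)
        n_ch = self.samples.shape[0]
        if self.channel_depth.shape != (n_ch,) or self.cortical_flag.shape != (n_ch,):
            raise ValueError("channel_depth / cortical_flag length must match channel count")
        if np.any(np.diff(self.channel_depth) <= 0):
            raise ValueError("channel_depth must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = ~np.isnan(self.samples)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.samples.shape:
            raise ValueError("valid_mask shape must match samples")
        # masked samples carry a NaN sentinel
        self.samples[~self.valid_mask] = np.nan

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class SpeedTrace:
    """Head speed (cm/s) sampled on a regular time base; NaN = invalid."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("speed values must be 1-D")
        if not self.fs > 0:
            raise ValueError("speed fs must be positive")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs

    def resampled(self, fs: float, n_samples: int) -> "SpeedTrace":
        """Linear resampling onto another regular time base (NaN propagates)."""
        if fs == self.fs and n_samples == self.values.size:
            return SpeedTrace(self.values.copy(), fs)
        t_new = np.arange(n_samples) / fs
        t_old = self.times()
        vals = np.interp(t_new, t_old, self.values)
        invalid = np.isnan(self.values)
        if invalid.any():
            bad = np.interp(t_new, t_old, invalid.astype(float)) > 0
            vals[bad] = np.nan
        return SpeedTrace(vals, fs)


@dataclass
class TrackingData:
    """Per-frame red/green head-LED positions in pixels."""

    red: np.ndarray    # (n_frames, 2)
    green: np.ndarray  # (n_frames, 2)
    fps: float
    valid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.shape != self.green.shape or self.red.ndim != 2 or self.red.shape[1] != 2:
            raise ValueError("red/green must both be (n_frames, 2)")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.valid is None:
            self.valid = np.ones(self.red.shape[0], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (self.red.shape[0],):
            raise ValueError("valid flags must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.red.shape[0]


@dataclass
class TrialRecord:
    """One behavioural trial of the approach-to-target task."""

    hold_start: float
    stimulus_onset: float
    modality: str            # "A" or "V"
    target_location: int
    response_time: float
    response_location: int
    correct: bool
    correction_trial: bool = False
    aborted: bool = False

    def __post_init__(self):
        if not self.aborted and not (self.hold_start < self.stimulus_onset < self.response_time):
            raise ValueError("non-aborted trial must satisfy hold_start < stimulus_onset < response_time")


_TRIAL_COLUMNS = [
    "hold_start", "stimulus_onset", "modality", "target_location",
    "response_time", "response_location", "correct", "correction_trial", "aborted",
]


@dataclass
class Session:
    """One recording session and its behavioural context."""

    recording: Recording
    species_profile: SpeciesProfile
    tracking: Optional[TrackingData] = None
    speed: Optional[SpeedTrace] = None
    trials: List[TrialRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.recording is None or self.recording.samples.size == 0:
            raise ValueError("session requires a non-empty recording")
        if self.speed is not None and self.speed.duration > self.recording.duration + 1.0 / self.recording.fs:
            raise ValueError("speed trace extends beyond the recording time span")
        drug = self.meta.get("drug", "none")
        if drug not in ("none", "atropine"):
            raise ValueError("drug condition flag must be 'none' or 'atropine'")


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in trials], columns=_TRIAL_COLUMNS)


def trials_from_frame(df: pd.DataFrame) -> List[TrialRecord]:
    return [TrialRecord(**{k: row[k] for k in _TRIAL_COLUMNS}) for _, row in df.iterrows()]


def save_session(session: Session, path, *, overwrite: bool = False) -> None:
    """Write ``session`` to an HDF5 container.

    Refuses to overwrite an existing file unless ``overwrite=True``.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    rec = session.recording
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("lfp", data=rec.samples.astype(np.float32))
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("channel_depth", data=rec.channel_depth)
        f.create_dataset("cortical_flag", data=rec.cortical_flag)
        f.create_dataset("valid_mask", data=rec.valid_mask)
        f.attrs["species"] = session.species_profile.name
        if session.speed is not None:
            d = f.create_dataset("speed", data=session.speed.values)
            d.attrs["fs"] = float(session.speed.fs)
        if session.tracking is not None:
            g = f.create_group("tracking")
            g.create_dataset("red", data=session.tracking.red)
            g.create_dataset("green", data=session.tracking.green)
            g.create_dataset("valid", data=session.tracking.valid)
            g.attrs["fps"] = float(session.tracking.fps)
        if session.trials:
            g = f.create_group("trials")
            df = trials_to_frame(session.trials)
            for col in _TRIAL_COLUMNS:
                data = df[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S8")
                g.create_dataset(col, data=data)
        meta = f.create_group("meta")
        for key, value in session.meta.items():
            meta.attrs[key] = json.dumps(value)


def load_session(path) -> Session:
    """Read a session container written by :func:`save_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unrecognised schema version {version}")
        for name in ("lfp", "fs", "channel_depth", "cortical_flag"):
            if name not in f:
                raise SchemaError(f"container missing mandatory dataset /{name}")
        fs = float(f["fs"][()])
        if fs <= 0:
            raise ValueError("fs must be positive")
        rec = Recording(
            samples=f["lfp"][()],
            fs=fs,
            channel_depth=f["channel_depth"][()],
            cortical_flag=f["cortical_flag"][()],
            valid_mask=f["valid_mask"][()] if "valid_mask" in f else None,
        )
        speed = None
        if "speed" in f:
            speed = SpeedTrace(f["speed"][()], float(f["speed"].attrs.get("fs", fs)))
        tracking = None
        if "tracking" in f:
            g = f["tracking"]
            tracking = TrackingData(g["red"][()], g["green"][()], float(g.attrs["fps"]), g["valid"][()])
        trials: List[TrialRecord] = []
        if "trials" in f:
            g = f["trials"]
            cols = {}
            for col in _TRIAL_COLUMNS:
                data = g[col][()]
                if data.dtype.kind == "S":
                    data = np.array([v.decode() for v in data])
                cols[col] = data
            df = pd.DataFrame(cols)
            for col in ("correct", "correction_trial", "aborted"):
                df[col] = df[col].astype(bool)
            for col in ("target_location", "response_location"):
                df[col] = df[col].astype(int)
            trials = trials_from_frame(df)
        meta = {k: json.loads(v) for k, v in f["meta"].attrs.items()} if "meta" in f else {}
        profile = get_profile(str(f.attrs.get("species", "rat")))
    return Session(recording=rec, species_profile=profile, tracking=tracking,
                   speed=speed, trials=trials, meta=meta)


# ---------------------------------------------------------------------------
# Epoch-table export

EPOCH_COLUMNS = [
    "start", "channel", "mean_speed", "state", "peak_range",
    "est_frequency", "trial_epoch", "valid",
]


def export_epoch_table(epochs: Sequence, path) -> None:
    """Write epoch records to CSV (one row per epoch, header included).

    Undefined numeric fields (NaN) are written as empty cells, not 0.
    """
    if len(epochs) == 0:
        raise ValueError("cannot export an empty epoch sequence")
    rows = [asdict(e) if not isinstance(e, dict) else e for e in epochs]
    df = pd.DataFrame(rows)
    cols = [c for c in EPOCH_COLUMNS if c in df.columns] + [c for c in df.columns if c not in EPOCH_COLUMNS]
    df[cols].to_csv(path, index=False, float_format="%.17g")


def import_epoch_table(path) -> pd.DataFrame:
    """Read back a CSV written by :func:`export_epoch_table`."""
    return pd.read_csv(path)
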