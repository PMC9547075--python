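"""Trial-epoch extraction and behavioural summaries.

Three 1 s task windows are analysed per trial: Hold (immobile nose-poke
before the stimulus, [onset - 1.05, onset - 0.05)), Run (the second
before the peripheral response) and Reward (the first post-response
second during which the head speed stays below 5 cm/s throughout —
"consistently below" is read strictly, every sample). Peak-range values
for these windows feed the trial-epoch mixed models; behavioural
performance is summarised as proportion correct against chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .acg import SineBank, autocorrelogram, match_sine, peak_range, prefilter_for_acg
from .profiles import SpeciesProfile
from .session import Session, SpeedTrace, TrialRecord

__all__ = ["TrialEpochWindow", "extract_trial_epochs", "epoch_condition_table",
           "behavioural_performance"]

log = logging.getLogger(__name__)

HOLD_OFFSET = (-1.05, -0.05)
EPOCH_LEN = 1.0


@dataclass
class TrialEpochWindow:
    """One 1 s trial window (channel-agnostic)."""

    trial: int
    label: str           # Hold | Run | Reward
    start: float
    end: float
    overlap: bool = False

    def __post_init__(self):
        if not np.isclose(self.end - self.start, EPOCH_LEN):
            raise ValueError("trial-epoch windows are exactly 1 s long")


def extract_trial_epochs(trials: Sequence[TrialRecord], speed: SpeedTrace,
                         immobile_threshold: float = 5.0,
                         include_errors: bool = False) -> List[TrialEpochWindow]:
    """Hold/Run/Reward windows for scored trials.

    Only correct, non-aborted, non-correction trials are used unless
    ``include_errors`` is set. The Reward window is the earliest 1 s
    window after the response with *every* speed sample below the
    immobility threshold, searched one speed sample at a time; trials
    where the animal never stills yield no Reward window.
    """
    v = speed.values
    fs = speed.fs
    win = int(round(EPOCH_LEN * fs))
    # prefix count of disqualifying samples (fast or invalid)
    bad = (~np.isfinite(v)) | (v >= immobile_threshold)
    csum = np.concatenate(([0], np.cumsum(bad)))
    duration = speed.duration
    windows: List[TrialEpochWindow] = []
    for idx, tr in enumerate(trials):
        if tr.aborted or tr.correction_trial or (not tr.correct and not include_errors):
            continue
        hold = (tr.stimulus_onset + HOLD_OFFSET[0], tr.stimulus_onset + HOLD_OFFSET[1])
        run = (tr.response_time - EPOCH_LEN, tr.response_time)
        overlap = run[0] < hold[1]
        if hold[0] >= 0 and hold[1] <= duration:
            windows.append(TrialEpochWindow(idx, "Hold", *hold, overlap=overlap))
        if run[0] >= 0 and run[1] <= duration:
            windows.append(TrialEpochWindow(idx, "Run", *run, overlap=overlap))
        i0 = int(np.ceil(tr.response_time * fs))
        reward = None
        for i in range(i0, v.size - win + 1):
            if csum[i + win] - csum[i] == 0:
                reward = (i / fs, i / fs + EPOCH_LEN)
                break
        if reward is not None and reward[1] <= duration:
            windows.append(TrialEpochWindow(idx, "Reward", *reward))
        elif reward is None:
            log.info("trial %d: no qualifying Reward window", idx)
    return windows


def epoch_condition_table(session: Session, windows: Sequence[TrialEpochWindow],
                          channels: Mapping[str, int],
                          profile: Optional[SpeciesProfile] = None,
                          normalise: bool = False,
                          subject: str = "S1", session_id: str = "s1") -> pd.DataFrame:
    """Peak range per trial-epoch window per channel.

    ``channels`` maps channel labels (e.g. ``"SO"``, ``"SRSLM"``) to
    channel indices. Windows containing masked LFP are dropped and
    counted (``attrs["n_dropped"]``). With ``normalise`` the peak range
    is divided by the session's median Run value per channel, so the
    median of normalised Run values is exactly 1.
    """
    profile = profile or session.species_profile
    fs = session.recording.fs
    bank = SineBank.build(profile, fs)
    speed = session.speed
    v = speed.resampled(fs, session.recording.n_samples).values if speed is not None else None
    rows = []
    n_dropped = 0
    for label, ch in channels.items():
        trace = prefilter_for_acg(session.recording.samples[ch], profile, fs)
        for w in windows:
            i0 = int(round(w.start * fs))
            i1 = i0 + int(round(EPOCH_LEN * fs))
            seg = trace[i0:i1]
            if seg.size < int(round(EPOCH_LEN * fs)) or not np.all(np.isfinite(seg)):
                n_dropped += 1
                continue
            acg = autocorrelogram(seg - seg.mean(), fs=fs)
            freq, ref = match_sine(acg, bank)
            pr = peak_range(acg, ref, freq, fs)
            mean_speed = float(np.nanmean(v[i0:i1])) if v is not None else np.nan
            rows.append({"trial": w.trial, "Epoch": w.label, "Chan": label,
                         "channel": ch, "peak_range": pr, "est_frequency": freq,
                         "mean_speed": mean_speed, "ID": subject, "Session": session_id})
    df = pd.DataFrame(rows)
    if normalise and len(df):
        for label in channels:
            sel = df["Chan"] == label
            run_median = df.loc[sel & (df["Epoch"] == "Run"), "peak_range"].median()
            df.loc[sel, "peak_range"] = df.loc[sel, "peak_range"] / run_median
    df.attrs["n_dropped"] = n_dropped
    return df


def behavioural_performance(sessions: Mapping[str, Sequence[TrialRecord]],
                            n_choices: int) -> Dict[str, object]:
    """Proportion correct per session/modality and a t-test against chance.

    Correction trials and aborted trials are excluded. The one-sample
    t-test compares session proportions to chance = 1/n_choices per
    modality; degenerate (zero-variance) cases are flagged instead of
    reporting a p-value.
    """
    rows = []
    for sid, trials in sessions.items():
        scored = [t for t in trials if not t.aborted and not t.correction_trial]
        if not scored:
            continue
        for modality in sorted({t.modality for t in scored}):
            sub = [t for t in scored if t.modality == modality]
            rows.append({"Session": sid, "modality": modality,
                         "n_trials": len(sub),
                         "proportion_correct": float(np.mean([t.correct for t in sub]))})
    if not rows:
        raise ValueError("no scored trials")
    table = pd.DataFrame(rows)
    chance = 1.0 / n_choices
    tests = {}
    for modality, grp in table.groupby("modality"):
        props = grp["proportion_correct"].to_numpy()
        if props.size < 2 or np.std(props) == 0:
            tests[modality] = {"t": np.nan, "p": np.nan, "flag": "degenerate variance"}
        else:
            t, p = sps.ttest_1samp(props, chance)
            tests[modality] = {"t": float(t), "p": float(p), "flag": ""}
    return {"table": table, "chance": chance, "tests": tests}
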