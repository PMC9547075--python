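"""Species-dependent analysis constants.

All species-specific parameters of the pipeline live in a single
:class:`SpeciesProfile`: theta filter band and FIR order, the IIR
pre-filters used before autocorrelation, the matched-sinusoid frequency
grid, channel-exclusion thresholds and the locomotor speed cutoffs.

Rat and ferret hippocampal theta occupy different frequency ranges
(roughly 6-12 Hz vs 4-7 Hz), so the filters and sinusoid grids differ
between the two species; everything downstream is parameterised by the
profile rather than by hard-coded constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml

__all__ = ["SpeciesProfile", "RAT", "FERRET", "get_profile", "profile_from_yaml"]


@dataclass(frozen=True)
class Cheby2HighpassSpec:
    """High-pass Chebyshev type II specification (applied zero-phase)."""

    order: int
    stopband_atten_db: float
    passband_edge_hz: float


@dataclass(frozen=True)
class NotchSpec:
    """Band-stop Chebyshev type II specification for mains rejection."""

    order: int = 14
    stopband_atten_db: float = 60.0
    stopband_hz: Tuple[float, float] = (49.0, 51.0)
    passband_hz: Tuple[float, float] = (48.0, 52.0)


@dataclass(frozen=True)
class SpeciesProfile:
    """All species-dependent constants used by the pipeline.

    Parameters
    ----------
    name
        ``"rat"`` or ``"ferret"``.
    theta_band
        Pass band (Hz) of the zero-lag FIR theta filter.
    theta_fir_order_s
        FIR filter order expressed as a duration in seconds; the filter
        order in taps is ``round(order_s * fs)`` (forced even so the
        group delay is an integer number of samples).
    hp_filter
        High-pass IIR applied (zero-phase) before epoch autocorrelation.
    notch_spec
        50 Hz band-stop applied together with ``hp_filter``.
    sine_grid
        ``(lo, hi, step)`` in Hz for the matched-sinusoid bank.
    theta_power_exclusion_db
        Channels whose theta-band PSD peak falls below this value (dB)
        are excluded from analysis.
    mains_margin_db
        Channels whose 50 Hz PSD peak exceeds the theta-band peak by
        more than this margin (dB) are excluded.
    psd_theta_band
        Band (Hz) within which the theta PSD peak is sought.
    move_threshold
        Locomotion threshold (cm/s) used for theta-on/off rules and for
        restricting depth profiles / regressions to running data.
    immobile_threshold, moving_epoch_threshold
        Conservative per-epoch mean-speed cutoffs (cm/s) that define the
        immobile (<) and moving (>) epoch classes; speeds in between are
        labelled intermediate and excluded from state contrasts.
    """

    name: str
    theta_band: Tuple[float, float]
    theta_fir_order_s: float
    hp_filter: Cheby2HighpassSpec
    notch_spec: NotchSpec
    sine_grid: Tuple[float, float, float]
    theta_power_exclusion_db: float
    mains_margin_db: float
    psd_theta_band: Tuple[float, float]
    move_threshold: float = 10.0
    immobile_threshold: float = 5.0
    moving_epoch_threshold: float = 20.0
    scratch_band: Tuple[float, float] = (6.0, 13.0)
    scratch_fir_order_s: float = 0.5
    scratch_threshold_factor: float = 8.0

    def as_dict(self) -> dict:
        return asdict(self)


RAT = SpeciesProfile(
    name="rat",
    theta_band=(4.0, 14.0),
    theta_fir_order_s=0.5,
    hp_filter=Cheby2HighpassSpec(order=6, stopband_atten_db=80.0, passband_edge_hz=2.0),
    notch_spec=NotchSpec(),
    sine_grid=(4.0, 14.0, 0.1),
    theta_power_exclusion_db=4.0,
    mains_margin_db=0.0,
    psd_theta_band=(6.0, 13.0),
)

FERRET = SpeciesProfile(
    name="ferret",
    theta_band=(2.0, 8.0),
    theta_fir_order_s=1.0,
    hp_filter=Cheby2HighpassSpec(order=4, stopband_atten_db=80.0, passband_edge_hz=1.0),
    notch_spec=NotchSpec(),
    sine_grid=(2.0, 14.0, 0.1),
    theta_power_exclusion_db=2.0,
    mains_margin_db=0.0,
    psd_theta_band=(4.0, 7.0),
)

_PROFILES = {"rat": RAT, "ferret": FERRET}


def get_profile(name: str) -> SpeciesProfile:
    """Return the default profile for ``name`` (``rat`` or ``ferret``)."""
    try:
        return _PROFILES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown species {name!r}; expected 'rat' or 'ferret'") from None


def profile_from_yaml(path) -> SpeciesProfile:
    """Load a profile from a YAML file.

    The file must contain a ``species`` key naming the base profile;
    any other top-level keys override the corresponding profile fields.
    Nested filter specs may be given as mappings.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = get_profile(cfg.pop("species", "rat"))
    fields = base.as_dict()
    for key, value in cfg.items():
        if key not in fields:
            raise ValueError(f"unknown profile field {key!r}")
        fields[key] = value
    hp = fields["hp_filter"]
    if isinstance(hp, dict):
        fields["hp_filter"] = Cheby2HighpassSpec(**hp)
    notch = fields["notch_spec"]
    if isinstance(notch, dict):
        notch = {k: tuple(v) if isinstance(v, list) else v for k, v in notch.items()}
        fields["notch_spec"] = NotchSpec(**notch)
    for key in ("theta_band", "sine_grid", "psd_theta_band", "scratch_band"):
        fields[key] = tuple(fields[key])
    return SpeciesProfile(**fields)
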