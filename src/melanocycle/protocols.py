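"""Light-stimulation protocols.

A protocol is a sequence of non-overlapping, time-ordered light segments
(onset, duration, irradiance in photons cm^-2 s^-1, wavelength in nm) over a
total recording window.  Presets reproduce the stimulation designs used
throughout the package: a repetition protocol of 0.1/1/10/60 s pulses each
repeated five times with 3-min dark gaps, single and paired 20-min pulses for
probing pigment regeneration, a 1-s pupillometry flash, and the stepped
irradiance series used in the neonatal phototaxis assay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError

#: irradiance used for all ex vivo MEA-style stimulation, photons cm^-2 s^-1
MEA_IRRADIANCE = 5e12
DEFAULT_WAVELENGTH_NM = 480.0


@dataclass(frozen=True)
class LightSegment:
    start_s: float
    duration_s: float
    irradiance: float
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class LightProtocol:
    """Timed light segments defining one stimulation experiment.

    Invariants (checked on construction): segments sorted by onset and
    non-overlapping, irradiance non-negative, every segment contained in
    ``[0, total_duration_s]``.
    """

    segments: list[LightSegment]
    total_duration_s: float
    interpulse_interval_s: float | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        segs = [s if isinstance(s, LightSegment) else LightSegment(*s) for s in self.segments]
        self.segments = segs
        last_end = 0.0
        for i, s in enumerate(segs):
            if s.irradiance < 0:
                raise ConfigurationError(f"segment {i}: irradiance must be >= 0")
            if s.duration_s <= 0:
                raise ConfigurationError(f"segment {i}: duration must be > 0")
            if s.start_s < last_end - 1e-12:
                raise ConfigurationError(
                    f"segment {i}: segments must be sorted and non-overlapping"
                )
            last_end = s.end_s
        if segs and last_end > self.total_duration_s + 1e-9:
            raise ConfigurationError("last segment ends after total_duration_s")
        if self.total_duration_s <= 0:
            raise ConfigurationError("total_duration_s must be > 0")

    def irradiance_at(self, t: np.ndarray) -> np.ndarray:
        """Photon flux at each time point (piecewise constant)."""
        t = np.asarray(t, dtype=float)
        phi = np.zeros_like(t)
        for s in self.segments:
            phi[(t >= s.start_s) & (t < s.end_s)] = s.irradiance
        return phi

    def breakpoints(self) -> list[float]:
        """Sorted unique times at which the photon flux can change."""
        pts = {0.0, float(self.total_duration_s)}
        for s in self.segments:
            pts.add(float(s.start_s))
            pts.add(float(s.end_s))
        return sorted(p for p in pts if 0.0 <= p <= self.total_duration_s)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "total_duration_s": self.total_duration_s,
            "interpulse_interval_s": self.interpulse_interval_s,
            "segments": [asdict(s) for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightProtocol":
        return cls(
            segments=[LightSegment(**s) for s in d["segments"]],
            total_duration_s=d["total_duration_s"],
            interpulse_interval_s=d.get("interpulse_interval_s"),
            name=d.get("name", "custom"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LightProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

REPETITION_DURATIONS_S = (0.1, 1.0, 10.0, 60.0)
N_REPETITIONS = 5
INTERPULSE_INTERVAL_S = 180.0


def protocol_repetition(
    lead_in_s: float = 180.0,
    gap_s: float = INTERPULSE_INTERVAL_S,
    irradiance: float = MEA_IRRADIANCE,
) -> LightProtocol:
    """Repetition protocol: 0.1, 1, 10 and 60 s pulses, five repetitions each,
    separated by 3 min of darkness (20 stimuli total)."""
    segments = []
    t = lead_in_s
    for dur in REPETITION_DURATIONS_S:
        for _ in range(N_REPETITIONS):
            segments.append(LightSegment(t, dur, irradiance))
            t += dur + gap_s
    return LightProtocol(segments, total_duration_s=t, interpulse_interval_s=gap_s,
                         name="protocol_repetition")


def protocol_single_pulse(
    duration_s: float,
    lead_in_s: float = 120.0,
    tail_s: float = 240.0,
    irradiance: float = MEA_IRRADIANCE,
) -> LightProtocol:
    """One pulse with dark lead-in and tail."""
    seg = LightSegment(lead_in_s, duration_s, irradiance)
    return LightProtocol([seg], total_duration_s=lead_in_s + duration_s + tail_s,
                         name=f"pulse_{duration_s:g}s")


def protocol_20min(lead_in_s: float = 120.0, tail_s: float = 300.0,
                   irradiance: float = MEA_IRRADIANCE) -> LightProtocol:
    """Continuous 20-min illumination, the regeneration-limited regime."""
    p = protocol_single_pulse(1200.0, lead_in_s=lead_in_s, tail_s=tail_s,
                              irradiance=irradiance)
    p.name = "protocol_20min"
    return p


def protocol_2x20min(lead_in_s: float = 120.0, gap_s: float = 300.0,
                     tail_s: float = 300.0,
                     irradiance: float = MEA_IRRADIANCE) -> LightProtocol:
    """Two successive 20-min pulses separated by a dark gap.

    A chromophore-supplementation event, when used, is placed mid-gap via the
    genotype configuration (see :func:`supplementation_time_2x20min`).
    """
    segs = [
        LightSegment(lead_in_s, 1200.0, irradiance),
        LightSegment(lead_in_s + 1200.0 + gap_s, 1200.0, irradiance),
    ]
    total = lead_in_s + 2 * 1200.0 + gap_s + tail_s
    return LightProtocol(segs, total_duration_s=total, name="protocol_2x20min_retinal")


def supplementation_time_2x20min(lead_in_s: float = 120.0, gap_s: float = 300.0) -> float:
    """Mid-gap time between the two 20-min pulses of :func:`protocol_2x20min`."""
    return lead_in_s + 1200.0 + gap_s / 2.0


def protocol_plr_1s(irradiance: float = 1e14) -> LightProtocol:
    """Pupillometry sequence: 1 min dark, 1 s light, 3 min dark."""
    return LightProtocol([LightSegment(60.0, 1.0, irradiance)],
                         total_duration_s=60.0 + 1.0 + 180.0, name="protocol_plr_1s")


PHOTOTAXIS_STEP_IRRADIANCES = (5e13, 5e14, 5e15)


def protocol_phototaxis_steps() -> LightProtocol:
    """Neonatal phototaxis assay: 2 min dark, three 2-min light steps at
    5e13 / 5e14 / 5e15 photons cm^-2 s^-1, 2 min dark."""
    segs = []
    t = 120.0
    for irr in PHOTOTAXIS_STEP_IRRADIANCES:
        segs.append(LightSegment(t, 120.0, irr))
        t += 120.0
    return LightProtocol(segs, total_duration_s=t + 120.0,
                         name="protocol_phototaxis_steps")


def protocol_phototaxis_rescue(irradiance: float = 5e14) -> LightProtocol:
    """Supplementation-rescue phototaxis variant: 2 min dark then 2 min light."""
    return LightProtocol([LightSegment(120.0, 120.0, irradiance)],
                         total_duration_s=240.0, name="protocol_phototaxis_rescue")


PRESETS = {
    "protocol_repetition": protocol_repetition,
    "protocol_20min": protocol_20min,
    "protocol_2x20min_retinal": protocol_2x20min,
    "protocol_plr_1s": protocol_plr_1s,
    "protocol_phototaxis_steps": protocol_phototaxis_steps,
    "protocol_phototaxis_rescue": protocol_phototaxis_rescue,
}


def get_preset(name: str) -> LightProtocol:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown protocol preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
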