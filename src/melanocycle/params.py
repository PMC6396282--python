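"""Kinetic, transduction and population parameters, with genotype presets.

The photocycle model tracks the total melanopsin pool across five states:

    dark  --sigma_act*Phi(t)-->  active  --k_phos-->  phospho_active
    phospho_active  --k_d2eff-->  arr_bound  --k_r1eff-->  dark
    active, phospho_active  --k_spont-->  spent  --k_turnover-->  dark

with the effective arrestin-dependent rates resolved per genotype:

    k_d2eff = (k_deact2 * arr2_level + k_deact_cross * arr1_level)
              * binding_scale * deact_accel
    k_r1eff = k_regen1 * arr1_level + k_regen_cross * arr2_level
              + retinal_supply_rate

beta-arrestin 2 drives deactivation of the phosphorylated signaling state,
beta-arrestin 1 drives chromophore exchange (regeneration) of the
arrestin-bound state; each weakly substitutes for the other (the cross
rates).  ``spent`` is an arrestin-independent dead end replenished only by
slow de novo pigment turnover; it carries the rundown seen under prolonged
illumination when deactivation is impaired.

Default rates are calibration constants of this package, chosen so that a
wild-type cell responding to a 60-s pulse shows ~2 s onset latency and a
post-light persistence of tens of seconds, and so that knockout genotypes
fall in their qualitative regimes (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .errors import ConfigurationError


@dataclass
class PhotocycleParams:
    """Base kinetic rates (s^-1) of the five-state pigment model.

    ``sigma_act`` converts photon flux (photons cm^-2 s^-1) into an
    activation rate; at the standard MEA irradiance of 5e12 the default gives
    0.08 s^-1.
    """

    sigma_act: float = 1.6e-14
    k_phos: float = 1.5
    k_deact2: float = 0.6
    k_deact_cross: float = 0.05
    k_spont: float = 0.0003
    k_regen1: float = 0.05
    k_regen_cross: float = 0.003
    k_turnover: float = 0.0005

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val < 0:
                raise ConfigurationError(f"rate {name} must be >= 0, got {val}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenotypeConfig:
    """Genotype-resolved modifiers of the photocycle.

    arr1_level/arr2_level are relative arrestin abundances (1 = wild type,
    0 = knockout, >1 = overexpression).  ``binding_scale`` attenuates the
    phospho-dependent arrestin rates for the alanine phosphosite mutants;
    ``deact_accel`` models the accelerated deactivation of the C-terminally
    truncated pigment.  ``supplementation_events`` are instantaneous
    (time_s, efficiency rho) chromophore deliveries that move a fraction rho
    of the bleached pools back to the dark state; ``retinal_supply_rate``
    models a sustained exogenous chromophore supply (in vivo injection) as a
    first-order return of both bleached pools to dark.
    """

    name: str = "WT"
    arr1_level: float = 1.0
    arr2_level: float = 1.0
    binding_scale: float = 1.0
    deact_accel: float = 1.0
    supplementation_events: list[tuple[float, float]] = field(default_factory=list)
    retinal_supply_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.arr1_level < 0 or self.arr2_level < 0:
            raise ConfigurationError("arrestin levels must be >= 0")
        if not 0.0 <= self.binding_scale <= 1.0:
            raise ConfigurationError("binding_scale must be in [0, 1]")
        if self.deact_accel < 1.0:
            raise ConfigurationError("deact_accel must be >= 1")
        if self.retinal_supply_rate < 0:
            raise ConfigurationError("retinal_supply_rate must be >= 0")
        self.supplementation_events = [
            (float(t), float(rho)) for t, rho in self.supplementation_events
        ]
        for t, rho in self.supplementation_events:
            if not 0.0 <= rho <= 1.0:
                raise ConfigurationError("supplementation efficiency must be in [0, 1]")

    # effective rates -----------------------------------------------------
    def k_d2eff(self, p: PhotocycleParams) -> float:
        return ((p.k_deact2 * self.arr2_level + p.k_deact_cross * self.arr1_level)
                * self.binding_scale * self.deact_accel)

    def k_r1eff(self, p: PhotocycleParams) -> float:
        return (p.k_regen1 * self.arr1_level + p.k_regen_cross * self.arr2_level
                + self.retinal_supply_rate)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenotypeConfig":
        d = dict(d)
        events = d.get("supplementation_events", [])
        d["supplementation_events"] = [tuple(e) for e in events]
        return cls(**d)


# phosphosite-mutant binding scales; monotone decrease with lost sites
BINDING_SCALES = {"WT": 1.0, "2A": 0.8, "4A": 0.6, "5A": 0.45, "7A": 0.2, "9A": 0.05}


def genotype(name: str, **overrides) -> GenotypeConfig:
    """Named genotype presets.

    Supported: WT, barr1_ko, barr2_ko, opn4_2a/4a/5a/7a/9a, opn4_d397,
    arr1_oe, arr2_oe.
    """
    key = name.lower()
    presets: dict[str, dict] = {
        "wt": {},
        "barr1_ko": {"arr1_level": 0.0},
        "barr2_ko": {"arr2_level": 0.0},
        "opn4_d397": {"deact_accel": 3.0},
        "arr1_oe": {"arr1_level": 3.0},
        "arr2_oe": {"arr2_level": 3.0},
    }
    for mut, scale in BINDING_SCALES.items():
        if mut != "WT":
            presets[f"opn4_{mut.lower()}"] = {"binding_scale": scale}
    if key not in presets:
        raise ConfigurationError(
            f"unknown genotype {name!r}; available: {sorted(presets)}"
        )
    cfg = dict(presets[key])
    cfg.update(overrides)
    return GenotypeConfig(name=name, **cfg)


@dataclass
class TransductionParams:
    """Map from pigment drive to firing rate.

    The drive D(t) = gain * (active + eps_phospho * phospho_active) is
    low-pass filtered with time constant ``tau_sig_s`` (cascade sluggishness),
    thresholded at ``theta`` and passed through a Hill function bounded by
    ``r_base`` and ``r_base + r_max``.
    """

    gain: float = 4.0
    eps_phospho: float = 1.0
    tau_sig_s: float = 1.5
    theta: float = 0.05
    r_base: float = 2.0
    r_max: float = 28.0
    hill_n: float = 2.0
    hill_K: float = 0.3
    t_refractory_s: float = 0.003

    def __post_init__(self) -> None:
        if self.r_base < 0:
            raise ConfigurationError("r_base must be >= 0")
        if self.r_max <= 0:
            raise ConfigurationError("r_max must be > 0")
        if self.tau_sig_s <= 0:
            raise ConfigurationError("tau_sig_s must be > 0")
        if not 0.0 <= self.eps_phospho <= 1.0:
            raise ConfigurationError("eps_phospho must be in [0, 1]")
        if self.t_refractory_s < 0:
            raise ConfigurationError("t_refractory_s must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PopulationConfig:
    """Population heterogeneity: lognormal per-cell pigment scaling and
    threshold scaling with the stated coefficients of variation."""

    n_cells: int = 30
    cv_pigment: float = 0.25
    cv_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.cv_pigment < 0 or self.cv_threshold < 0:
            raise ConfigurationError("CVs must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PupilParams:
    """First-order pupil dynamics: diameter relaxes toward
    d_dark * (1 - c_max * S(drive)) with time constant tau_pupil_s, where
    S(x) = x / (x + half_sat) saturates in [0, 1)."""

    d_dark: float = 2.0          # mm
    c_max: float = 0.75
    tau_pupil_s: float = 1.5
    half_sat: float = 0.15

    def __post_init__(self) -> None:
        if self.d_dark <= 0 or self.tau_pupil_s <= 0 or self.half_sat <= 0:
            raise ConfigurationError("pupil parameters must be positive")
        if not 0.0 <= self.c_max < 1.0:
            raise ConfigurationError("c_max must be in [0, 1)")


@dataclass
class TrackParams:
    """Random-walk locomotion of a pup whose step length is suppressed by
    the photoreceptor drive: step = base_speed * (1 - s_max * S(drive))."""

    fps: float = 30.0
    base_speed_px: float = 2.0   # mean step length per frame, pixels
    s_max: float = 0.6
    half_sat: float = 0.15

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.base_speed_px < 0 or self.half_sat <= 0:
            raise ConfigurationError("track parameters invalid")
        if not 0.0 <= self.s_max <= 1.0:
            raise ConfigurationError("s_max must be in [0, 1]")


@dataclass
class DetectionParams:
    """Spike-detection settings: negative threshold at ``threshold_mult``
    noise SDs, 1 ms pre / 2 ms post cutouts, 1 ms dead time."""

    threshold_mult: float = 5.0
    cutout_pre_s: float = 0.001
    cutout_post_s: float = 0.002
    dead_time_s: float = 0.001

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
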