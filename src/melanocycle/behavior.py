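"""Negative-phototaxis and pupillary-light-reflex quantification.

Phototaxis: head-tracking coordinates are reduced to the distance covered
per 1-s bin; pups whose mean dark-period activity falls below 5 pixels/bin
are excluded; light-period activity is normalized to the dark period.

Pupillometry: diameter traces are normalized to the mean over the first
minute of darkness; constriction at time t is 100 * (1 - d(t)/baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior_sim import TrackingTrace
from .errors import InputError

EXCLUSION_THRESHOLD_PX = 5.0
DARK_WINDOW_S = 120.0


def activity_profile(track: TrackingTrace, bin_s: float = 1.0) -> np.ndarray:
    """Euclidean path length per time bin.

    The step ending at frame i is assigned to the bin containing that
    frame's time, so the profile sums exactly to the total path length.
    """
    pos = np.asarray(track.positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or not np.all(np.isfinite(pos)):
        raise InputError("positions must be a finite (n, 2) array")
    n = pos.shape[0]
    duration = n / track.fps
    n_bins = int(np.ceil(duration / bin_s))
    profile = np.zeros(n_bins)
    if n < 2:
        return profile
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    t = np.arange(1, n) / track.fps
    bins = np.minimum((t / bin_s).astype(int), n_bins - 1)
    np.add.at(profile, bins, steps)
    return profile


@dataclass
class PhototaxisResult:
    profile: np.ndarray
    dark_mean: float
    light_mean: float | None
    normalized_light_activity: float | None
    excluded: bool
    per_step_normalized: dict[str, float] = field(default_factory=dict)


def phototaxis_metrics(profile: np.ndarray, light_on_s: float,
                       light_off_s: float | None = None,
                       exclusion_threshold: float = EXCLUSION_THRESHOLD_PX,
                       bin_s: float = 1.0,
                       step_bounds_s: list[float] | None = None,
                       dark_window_s: float = DARK_WINDOW_S) -> PhototaxisResult:
    """Dark/light activity comparison with the 5 px/bin exclusion rule.

    ``dark_mean`` is the mean over the 2 min preceding light ON; pups with
    ``dark_mean`` below the threshold are excluded (no normalized value).
    ``normalized_light_activity`` = light-period mean / dark mean.  When
    ``step_bounds_s`` gives irradiance-step boundaries, a per-step
    normalized activity is also returned.
    """
    profile = np.asarray(profile, dtype=float)
    on_bin = int(round(light_on_s / bin_s))
    dark_bins = int(round(dark_window_s / bin_s))
    if on_bin < dark_bins:
        raise InputError(
            f"need {dark_window_s:g} s of recording before light ON")
    dark = profile[on_bin - dark_bins:on_bin]
    dark_mean = float(dark.mean())
    if dark_mean < exclusion_threshold:
        return PhototaxisResult(profile, dark_mean, None, None, True)
    off_bin = int(round(light_off_s / bin_s)) if light_off_s is not None \
        else profile.size
    light = profile[on_bin:off_bin]
    light_mean = float(light.mean())
    per_step = {}
    if step_bounds_s:
        bounds = [light_on_s] + list(step_bounds_s)
        for j, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
            seg = profile[int(round(a / bin_s)):int(round(b / bin_s))]
            per_step[f"step_{j}"] = float(seg.mean() / dark_mean)
    return PhototaxisResult(profile, dark_mean, light_mean,
                            light_mean / dark_mean, False, per_step)


# ---------------------------------------------------------------------------
# Pupillary light reflex
# ---------------------------------------------------------------------------

def normalize_pupil(trace: np.ndarray, fps: float,
                    dark_window_s: float = 60.0) -> tuple[np.ndarray, float]:
    """Divide a diameter trace by its mean over the initial dark window."""
    trace = np.asarray(trace, dtype=float)
    n_base = int(round(dark_window_s * fps))
    if n_base < 1 or n_base > trace.size:
        raise InputError("baseline window outside trace")
    baseline = float(trace[:n_base].mean())
    if baseline <= 0:
        raise InputError("baseline diameter must be positive")
    return trace / baseline, baseline


@dataclass
class PLRMetrics:
    max_constriction_pct: float
    mean_constriction_1min_pct: float
    relaxation_pct: float | None     # constriction 1 min after light OFF


def plr_metrics(normalized: np.ndarray, fps: float, stim_on_s: float,
                stim_dur_s: float) -> PLRMetrics:
    """Constriction metrics from a baseline-normalized pupil trace.

    Constriction(t) = 100 * (1 - normalized(t)).  Maximum constriction is
    taken over the stimulus plus the following minute, the mean over the
    minute following stimulus onset, and relaxation is the constriction
    remaining one minute after light OFF (None when the trace ends sooner).
    """
    x = np.asarray(normalized, dtype=float)
    constriction = 100.0 * (1.0 - x)
    i_on = int(round(stim_on_s * fps))
    i_off = int(round((stim_on_s + stim_dur_s) * fps))
    i_min = int(round((stim_on_s + stim_dur_s + 60.0) * fps))
    window = constriction[i_on:min(i_min, x.size)]
    if window.size == 0:
        raise InputError("stimulus window outside trace")
    max_c = float(window.max())
    i_1min = int(round((stim_on_s + 60.0) * fps))
    mean_c = float(constriction[i_on:min(i_1min, x.size)].mean())
    i_relax = int(round((stim_on_s + stim_dur_s + 60.0) * fps))
    relax = float(constriction[i_relax]) if i_relax < x.size else None
    return PLRMetrics(max_c, mean_c, relax)
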