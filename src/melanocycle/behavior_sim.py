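"""Behavioral readout simulators: pupil dynamics and pup locomotion.

Both are driven by the low-pass-filtered photoreceptor drive of a simulated
retina.  The pupil relaxes with first-order kinetics toward a
drive-dependent target diameter; the pup performs a 2-D random walk whose
step length is suppressed by the drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .params import PupilParams, TrackParams


def saturating(x: np.ndarray, half_sat: float) -> np.ndarray:
    """Monotone map of non-negative drive into [0, 1)."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    return x / (x + half_sat)


def simulate_pupil(drive: np.ndarray, dt: float,
                   pp: PupilParams | None = None,
                   d0: float | None = None) -> np.ndarray:
    """Pupil diameter trace under a drive series.

    d'(t) = (target(t) - d) / tau_pupil with
    target = d_dark * (1 - c_max * S(drive)); integrated with the exact
    exponential update per step, so diameter stays in (0, d_dark].
    """
    pp = pp or PupilParams()
    target = pp.d_dark * (1.0 - pp.c_max * saturating(drive, pp.half_sat))
    a = float(np.exp(-dt / pp.tau_pupil_s))
    cur = pp.d_dark if d0 is None else float(d0)
    # d_i = (1 - a) * target_i + a * d_{i-1}: a first-order IIR filter
    d, _ = signal.lfilter([1.0 - a], [1.0, -a], target, zi=np.array([a * cur]))
    return d


@dataclass
class TrackingTrace:
    """Head-centroid positions (pixels) at a fixed frame rate."""

    fps: float
    positions: np.ndarray       # (n_frames, 2)
    light_on_s: float | None = None
    light_off_s: float | None = None


def suppression_factor(drive: np.ndarray, tk: TrackParams) -> np.ndarray:
    """Locomotor suppression in (0, 1]: 1 in darkness, 1 - s_max at
    saturating drive."""
    return 1.0 - tk.s_max * saturating(drive, tk.half_sat)


def simulate_phototaxis(drive: np.ndarray, dt: float,
                        tk: TrackParams | None = None,
                        seed: int | np.random.Generator = 0,
                        light_on_s: float | None = None,
                        light_off_s: float | None = None,
                        suppression: np.ndarray | None = None) -> TrackingTrace:
    """Light-suppressed random-walk locomotion track.

    Per frame, the step length is base_speed_px * suppression * E with
    E ~ Exponential(1) (so the mean per-frame step is base_speed_px *
    suppression) in a uniformly random direction.  ``suppression`` overrides
    the drive-derived factor when given (useful for fixtures).
    """
    tk = tk or TrackParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = drive.size * dt
    n_frames = int(round(duration * tk.fps))
    frame_t = np.arange(n_frames) / tk.fps
    if suppression is None:
        drive_f = np.interp(frame_t, np.arange(drive.size) * dt, drive)
        supp = suppression_factor(drive_f, tk)
    else:
        supp = np.broadcast_to(np.asarray(suppression, dtype=float), (n_frames,))
    steps = tk.base_speed_px * supp * rng.exponential(1.0, size=n_frames)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_frames)
    dxy = np.column_stack([steps * np.cos(angles), steps * np.sin(angles)])
    positions = np.vstack([[0.0, 0.0], np.cumsum(dxy, axis=0)])[:-1]
    return TrackingTrace(fps=tk.fps, positions=positions,
                         light_on_s=light_on_s, light_off_s=light_off_s)
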