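"""Drive-to-rate transduction, stochastic spike generation and raw-trace
synthesis.

The phototransduction cascade is summarized by a first-order low-pass filter
on the pigment drive followed by a thresholded Hill nonlinearity; spikes are
drawn from an inhomogeneous Poisson process by thinning with an absolute
refractory period; raw MEA-like traces are Gaussian noise at 10 kHz with a
biphasic negative-peak waveform added at every spike time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, InputError
from .params import TransductionParams


@dataclass
class SpikeTrain:
    """Sorted event times of a single cell."""

    cell_id: str
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise InputError(f"{self.cell_id}: spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass
class RawTrace:
    """10 kHz voltage trace with optional embedded ground truth."""

    samples: np.ndarray
    sampling_rate_hz: float = 10_000.0
    true_spike_times_s: np.ndarray | None = None
    noise_sd: float | None = None

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


def lowpass_drive(drive: np.ndarray, dt: float, tau_s: float) -> np.ndarray:
    """Exact discrete first-order low-pass (zero initial state)."""
    alpha = float(np.exp(-dt / tau_s))
    return signal.lfilter([1.0 - alpha], [1.0, -alpha], drive)


def drive_to_rate(drive: np.ndarray, dt: float,
                  tp: TransductionParams | None = None,
                  theta: float | None = None) -> np.ndarray:
    """Firing rate (Hz) from the drive series.

    r(t) = r_base + r_max * u^n / (K^n + u^n) with u = max(0, D_filt - theta);
    output is bounded in [r_base, r_base + r_max] and monotone in the drive.
    """
    tp = tp or TransductionParams()
    drive = np.asarray(drive, dtype=float)
    if np.any(drive < 0):
        raise ConfigurationError("drive must be non-negative")
    theta = tp.theta if theta is None else theta
    filt = lowpass_drive(drive, dt, tp.tau_sig_s)
    u = np.maximum(0.0, filt - theta)
    un = u ** tp.hill_n
    return tp.r_base + tp.r_max * un / (tp.hill_K ** tp.hill_n + un)


def generate_spikes(rate: np.ndarray, dt: float,
                    tp: TransductionParams | None = None,
                    seed: int | np.random.Generator = 0,
                    cell_id: str = "cell_0") -> SpikeTrain:
    """Inhomogeneous Poisson spikes by thinning, with absolute refractoriness.

    Homogeneous candidates at the peak rate are thinned with probability
    rate(t)/rate_max; candidates within ``t_refractory_s`` of the last
    accepted spike are discarded.  Identical seed yields identical trains.
    """
    tp = tp or TransductionParams()
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ConfigurationError("rate must be non-negative everywhere")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = rate.size * dt
    lam_max = float(rate.max(initial=0.0))
    if lam_max == 0.0:
        return SpikeTrain(cell_id, np.empty(0))
    n_cand = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    accept_u = rng.uniform(0.0, 1.0, size=n_cand)
    idx = np.minimum((cand / dt).astype(np.int64), rate.size - 1)
    keep = accept_u < rate[idx] / lam_max
    times = []
    t_last = -np.inf
    t_ref = tp.t_refractory_s
    for t, ok in zip(cand, keep):
        if ok and t - t_last > t_ref:
            times.append(t)
            t_last = t
    return SpikeTrain(cell_id, np.asarray(times))


# ---------------------------------------------------------------------------
# Raw-trace synthesis
# ---------------------------------------------------------------------------

def spike_template(sampling_rate_hz: float = 10_000.0) -> np.ndarray:
    """Biphasic extracellular waveform, ~1.2 ms, normalized to a -1 trough.

    A Gabor-like shape: fast negative deflection followed by a smaller
    positive overshoot, the canonical extracellular action-potential
    signature on a MEA channel.
    """
    t = np.arange(-0.4e-3, 0.8e-3, 1.0 / sampling_rate_hz)
    w = -np.sin(2 * np.pi * t / 1.2e-3) * np.exp(-(t / 0.35e-3) ** 2)
    return w / np.abs(w.min())


def template_trough_offset(sampling_rate_hz: float = 10_000.0) -> int:
    """Sample index of the trough within :func:`spike_template`."""
    return int(np.argmin(spike_template(sampling_rate_hz)))


def synthesize_raw_trace(train: SpikeTrain, duration_s: float,
                         noise_sd: float = 1.0, amplitude: float = 8.0,
                         seed: int | np.random.Generator = 0,
                         sampling_rate_hz: float = 10_000.0) -> RawTrace:
    """Gaussian noise with the spike template added at each spike time.

    ``amplitude`` is the trough depth in units of ``noise_sd`` (absolute
    units when ``noise_sd`` is zero).  Spike times are aligned so the
    template trough falls on the nearest sample to the true time;
    overlapping templates are summed.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    trace = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    tmpl = spike_template(sampling_rate_hz)
    trough = int(np.argmin(tmpl))
    scale = amplitude * (noise_sd if noise_sd > 0 else 1.0)
    for t in train.times_s:
        center = int(round(t * sampling_rate_hz))
        start = center - trough
        lo, hi = max(0, start), min(n, start + tmpl.size)
        if lo < hi:
            trace[lo:hi] += scale * tmpl[lo - start:hi - start]
    return RawTrace(samples=trace, sampling_rate_hz=sampling_rate_hz,
                    true_spike_times_s=train.times_s.copy(), noise_sd=noise_sd)
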