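"""Extracellular spike detection and response quantification.

Detection follows the standard MEA convention: a negative threshold at a
multiple (default 5) of the channel noise SD, with the noise SD estimated
robustly so embedded spikes do not inflate it; events are aligned to the
trough of each sub-threshold excursion, a dead time suppresses retriggering,
and 1 ms pre / 2 ms post cutouts are extracted.

Response quantification bins spikes into a peristimulus time histogram and
applies the onset criterion of the discharge rate rising above the
pre-stimulus baseline by two standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError
from .params import DetectionParams
from .transduction import RawTrace, SpikeTrain


def estimate_noise_sd(trace: RawTrace) -> float:
    """Robust noise SD via the scaled median absolute deviation.

    MAD / Phi^-1(3/4) is a consistent estimator of the Gaussian SD and is
    essentially unaffected by sparse large-amplitude spike waveforms.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size < trace.sampling_rate_hz:  # < 1 s of data
        raise InputError("trace must be at least 1 s long for noise estimation")
    return float(stats.median_abs_deviation(x, scale="normal"))


@dataclass
class DetectionResult:
    train: SpikeTrain
    cutouts: np.ndarray            # (n_events, n_samples)
    threshold: float               # absolute voltage threshold (negative)
    noise_sd: float
    padded: np.ndarray             # bool flag per event: cutout hit a boundary


def detect_spikes(trace: RawTrace, dp: DetectionParams | None = None,
                  noise_sd: float | None = None,
                  cell_id: str = "cell_0") -> DetectionResult:
    """Threshold-crossing detection with trough alignment and dead time.

    An event is a maximal run of samples below ``-threshold_mult * SD``;
    its time is the trace minimum within that excursion.  Events whose
    trough falls within ``dead_time_s`` of the previous accepted event are
    suppressed.  Cutouts extending past the trace bounds are zero-padded
    and flagged rather than dropped.
    """
    dp = dp or DetectionParams()
    x = np.asarray(trace.samples, dtype=float)
    fs = trace.sampling_rate_hz
    sd = estimate_noise_sd(trace) if noise_sd is None else float(noise_sd)
    thr = -dp.threshold_mult * sd

    below = x < thr
    # excursion boundaries
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below.size and below[0]:
        starts = np.r_[0, starts]
    if below.size and below[-1]:
        ends = np.r_[ends, below.size]

    dead = dp.dead_time_s * fs
    troughs: list[int] = []
    last = -np.inf
    for s, e in zip(starts, ends):
        i = s + int(np.argmin(x[s:e]))
        if i - last > dead:
            troughs.append(i)
            last = i

    n_pre = int(round(dp.cutout_pre_s * fs))
    n_post = int(round(dp.cutout_post_s * fs))
    cutouts = np.zeros((len(troughs), n_pre + n_post))
    padded = np.zeros(len(troughs), dtype=bool)
    for k, i in enumerate(troughs):
        lo, hi = i - n_pre, i + n_post
        clo, chi = max(0, lo), min(x.size, hi)
        cutouts[k, clo - lo:chi - lo] = x[clo:chi]
        padded[k] = (lo < 0) or (hi > x.size)

    times = np.asarray(troughs, dtype=float) / fs
    return DetectionResult(train=SpikeTrain(cell_id, times), cutouts=cutouts,
                           threshold=thr, noise_sd=sd, padded=padded)


# ---------------------------------------------------------------------------
# PSTH and response metrics
# ---------------------------------------------------------------------------

@dataclass
class PSTH:
    """Uniformly binned firing rate: ``rates[i]`` covers
    [t0 + i*bin_s, t0 + (i+1)*bin_s)."""

    bin_s: float
    rates: np.ndarray
    t0: float = 0.0

    @property
    def edges(self) -> np.ndarray:
        return self.t0 + np.arange(self.rates.size + 1) * self.bin_s


@dataclass
class BaselineStats:
    mean_hz: float
    sd_hz: float
    window: tuple[float, float]


def compute_psth(train: SpikeTrain, bin_s: float,
                 window: tuple[float, float]) -> PSTH:
    """Spike counts per bin divided by the bin width."""
    t0, t1 = window
    if t1 <= t0 or bin_s <= 0:
        raise InputError("window must be increasing and bin_s > 0")
    n_bins = int(round((t1 - t0) / bin_s))
    edges = t0 + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(train.times_s, bins=edges)
    return PSTH(bin_s=bin_s, rates=counts / bin_s, t0=t0)


def baseline_stats(psth: PSTH, window: tuple[float, float]) -> BaselineStats:
    """Mean and SD of the PSTH rate over a pre-stimulus window."""
    sel = (psth.edges[:-1] >= window[0] - 1e-9) & (psth.edges[1:] <= window[1] + 1e-9)
    rates = psth.rates[sel]
    if rates.size == 0:
        raise InputError("baseline window contains no full PSTH bin")
    return BaselineStats(mean_hz=float(rates.mean()),
                         sd_hz=float(rates.std(ddof=0)), window=window)


@dataclass
class ResponseMetrics:
    """Per-cell, per-stimulus response quantification."""

    responded: bool
    onset_latency_s: float | None
    duration_s: float
    n_spikes: int
    mean_rate_hz: float
    end_s: float | None = None          # absolute end of the response window
    threshold_hz: float | None = None
    sd_floored: bool = False


def extract_response(psth: PSTH, baseline: BaselineStats, stim_onset_s: float,
                     train: SpikeTrain | None = None,
                     stim_duration_s: float | None = None,
                     m_onset_bins: int = 2, gap_bins: int = 4,
                     sd_floor_hz: float | None = None) -> ResponseMetrics:
    """Apply the 2-SD onset criterion and measure the response extent.

    Onset is the start of the first run of at least ``m_onset_bins``
    consecutive bins exceeding baseline mean + 2 SD at or after stimulus
    onset.  The response extends while bins stay supra-threshold, tolerating
    gaps of at most ``gap_bins`` sub-threshold bins.  ``n_spikes`` counts
    spikes inside [onset, end] when a train is supplied, otherwise
    integrates the PSTH.  A zero baseline SD falls back to ``sd_floor_hz``
    (flagged); with no floor supplied, 1/bin-width Hz (one spike per bin) is
    used.
    """
    sd = baseline.sd_hz
    floored = False
    if sd == 0.0:
        sd = sd_floor_hz if sd_floor_hz is not None else 1.0 / psth.bin_s
        floored = True
    thr = baseline.mean_hz + 2.0 * sd

    starts = psth.edges[:-1]
    supra = psth.rates > thr
    eligible = starts >= stim_onset_s - 1e-9
    idx = np.flatnonzero(supra & eligible)

    onset_bin = None
    for i in idx:
        j = i + m_onset_bins
        if j <= supra.size and supra[i:j].all():
            onset_bin = i
            break
    if onset_bin is None:
        mean_rate = _mean_rate(psth, train, stim_onset_s, stim_duration_s)
        return ResponseMetrics(False, None, 0.0, 0, mean_rate,
                               threshold_hz=thr, sd_floored=floored)

    # extend while supra-threshold with tolerated gaps
    end_bin = onset_bin
    gap = 0
    for i in range(onset_bin + 1, supra.size):
        if supra[i]:
            end_bin = i
            gap = 0
        else:
            gap += 1
            if gap > gap_bins:
                break
    onset_t = float(starts[onset_bin])
    end_t = float(psth.edges[end_bin + 1])
    if train is not None:
        n_spikes = int(np.count_nonzero(
            (train.times_s >= onset_t) & (train.times_s <= end_t)))
    else:
        sel = slice(onset_bin, end_bin + 1)
        n_spikes = int(round(float(psth.rates[sel].sum() * psth.bin_s)))
    mean_rate = _mean_rate(psth, train, stim_onset_s, stim_duration_s)
    return ResponseMetrics(True, onset_t - stim_onset_s, end_t - onset_t,
                           n_spikes, mean_rate, end_s=end_t,
                           threshold_hz=thr, sd_floored=floored)


def _mean_rate(psth: PSTH, train: SpikeTrain | None, stim_onset_s: float,
               stim_duration_s: float | None) -> float:
    """Mean discharge rate over the stimulus window (0 when unknown)."""
    if stim_duration_s is None:
        return 0.0
    t0, t1 = stim_onset_s, stim_onset_s + stim_duration_s
    if train is not None:
        n = np.count_nonzero((train.times_s >= t0) & (train.times_s < t1))
        return float(n / stim_duration_s)
    sel = (psth.edges[:-1] >= t0 - 1e-9) & (psth.edges[1:] <= t1 + 1e-9)
    return float(psth.rates[sel].mean()) if sel.any() else 0.0
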