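"""Per-stimulus response metrics over a full stimulation protocol.

Bridges spike trains and the adaptation analyses: for every light segment of
a protocol, a peristimulus histogram is built from a pre-stimulus baseline
window through the following dark gap, the 2-SD onset criterion is applied,
and one row of metrics is emitted per (cell, stimulus, repetition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detection import baseline_stats, compute_psth, extract_response
from .protocols import LightProtocol
from .transduction import SpikeTrain

DEFAULT_BIN_S = 0.5
DEFAULT_BASELINE_S = 60.0

METRIC_COLUMNS = ["cell_id", "stimulus_duration_s", "repetition_index",
                  "stim_onset_s", "responded", "latency_s", "duration_s",
                  "post_off_duration_s", "n_spikes", "mean_rate_hz"]


def repetition_indices(protocol: LightProtocol) -> list[int]:
    """1-based repetition index per segment, counted within equal durations."""
    seen: dict[float, int] = {}
    out = []
    for seg in protocol.segments:
        key = round(seg.duration_s, 9)
        seen[key] = seen.get(key, 0) + 1
        out.append(seen[key])
    return out


def response_table(trains: list[SpikeTrain], protocol: LightProtocol,
                   bin_s: float = DEFAULT_BIN_S,
                   baseline_s: float = DEFAULT_BASELINE_S,
                   m_onset_bins: int = 2, gap_bins: int = 4,
                   sd_floor_hz: float | None = None) -> pd.DataFrame:
    """Response metrics for every (cell, stimulus segment).

    The analysis window of a segment runs from ``baseline_s`` before its
    onset to the next segment's onset (or the end of the recording), so
    post-light persistence is measured in the dark gap.
    ``post_off_duration_s`` is the part of the response extending beyond
    light OFF.
    """
    reps = repetition_indices(protocol)
    rows = []
    for train in trains:
        for seg, rep in zip(protocol.segments, reps):
            next_onsets = [s.start_s for s in protocol.segments
                           if s.start_s > seg.start_s]
            win_end = min(next_onsets) if next_onsets else protocol.total_duration_s
            win_start = max(0.0, seg.start_s - baseline_s)
            psth = compute_psth(train, bin_s, (win_start, win_end))
            base = baseline_stats(psth, (win_start, seg.start_s))
            m = extract_response(psth, base, seg.start_s, train=train,
                                 stim_duration_s=seg.duration_s,
                                 m_onset_bins=m_onset_bins, gap_bins=gap_bins,
                                 sd_floor_hz=sd_floor_hz)
            post_off = 0.0
            if m.responded and m.end_s is not None:
                post_off = max(0.0, m.end_s - seg.end_s)
            rows.append({
                "cell_id": train.cell_id,
                "stimulus_duration_s": seg.duration_s,
                "repetition_index": rep,
                "stim_onset_s": seg.start_s,
                "responded": m.responded,
                "latency_s": m.onset_latency_s if m.responded else np.nan,
                "duration_s": m.duration_s,
                "post_off_duration_s": post_off,
                "n_spikes": m.n_spikes,
                "mean_rate_hz": m.mean_rate_hz,
            })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
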