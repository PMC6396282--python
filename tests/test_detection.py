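"""Spike detection against brute-force oracles and the 2-SD response
criterion on constructed histograms."""

import numpy as np
import pytest
from scipy.stats import norm

from melanocycle import DetectionParams
from melanocycle.detection import (BaselineStats, PSTH, baseline_stats,
                                   compute_psth, detect_spikes,
                                   estimate_noise_sd, extract_response)
from melanocycle.errors import InputError
from melanocycle.transduction import RawTrace, SpikeTrain, synthesize_raw_trace


def brute_force_detect(x, thr, dead_samples):
    """Naive full-scan reference detector: walk every sample, find threshold
    excursions, align to the excursion minimum, honor the dead time."""
    events = []
    i, n = 0, len(x)
    last = -np.inf
    while i < n:
        if x[i] < thr:
            j = i
            while j < n and x[j] < thr:
                j += 1
            trough = i + int(np.argmin(x[i:j]))
            if trough - last > dead_samples:
                events.append(trough)
                last = trough
            i = j
        else:
            i += 1
    return events


class TestNoiseSD:
    def test_constant_trace_zero(self):
        assert estimate_noise_sd(RawTrace(np.zeros(20000))) == 0.0

    def test_gaussian_trace_within_two_percent(self, rng):
        x = rng.normal(0, 3.0, 600_000)
        assert estimate_noise_sd(RawTrace(x)) == pytest.approx(3.0, rel=0.02)

    def test_robust_to_embedded_spikes(self, rng):
        """20 Hz of 10x-SD spikes shift the raw SD but not the MAD."""
        train = SpikeTrain("c", np.arange(0.025, 60.0, 0.05))
        trace = synthesize_raw_trace(train, 60.0, noise_sd=1.0, amplitude=10.0,
                                     seed=6)
        assert estimate_noise_sd(trace) == pytest.approx(1.0, rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(InputError):
            estimate_noise_sd(RawTrace(np.zeros(100)))


class TestDetectSpikes:
    def test_matches_brute_force_on_seeded_traces(self):
        dp = DetectionParams()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_spk = rng.integers(20, 60)
            times = np.sort(rng.uniform(0.1, 59.9, n_spk))
            times = times[np.r_[True, np.diff(times) > 0.004]]
            trace = synthesize_raw_trace(SpikeTrain("c", times), 60.0,
                                         noise_sd=1.0, amplitude=9.0, seed=seed)
            res = detect_spikes(trace, dp)
            oracle = brute_force_detect(trace.samples, res.threshold,
                                        dp.dead_time_s * trace.sampling_rate_hz)
            got = np.round(res.train.times_s * trace.sampling_rate_hz).astype(int)
            assert np.array_equal(got, oracle)

    def test_inserted_spikes_all_recovered_with_small_jitter(self):
        dp = DetectionParams()
        rng = np.random.default_rng(21)
        times = np.sort(rng.uniform(0.1, 59.9, 40))
        times = times[np.r_[True, np.diff(times) > 0.003]]
        trace = synthesize_raw_trace(SpikeTrain("c", times), 60.0,
                                     noise_sd=1.0, amplitude=8.0, seed=21)
        res = detect_spikes(trace, dp)
        assert len(res.train) == len(times)
        jitter = np.abs(res.train.times_s - times)
        assert jitter.max() <= 0.3e-3

    def test_pure_noise_false_events_bounded_by_gaussian_tail(self):
        """Expected down-crossings of -5 sigma for white Gaussian noise:
        N * p * (1 - p) with p the one-sided tail probability; observed
        count over 20 traces must stay within 3x that analytic expectation."""
        dp = DetectionParams()
        n = 600_000
        p_tail = norm.cdf(-dp.threshold_mult)
        expected_per_trace = n * p_tail * (1 - p_tail)
        total, total_expected = 0, 0.0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            trace = RawTrace(rng.normal(0, 1.0, n))
            res = detect_spikes(trace, dp, noise_sd=1.0)
            total += len(res.train)
            total_expected += expected_per_trace
        assert total <= 3 * total_expected

    def test_translation_equivariance(self, rng):
        dp = DetectionParams()
        x = rng.normal(0, 1.0, 20000)
        x[5000] = -10.0
        shift = 3000
        a = detect_spikes(RawTrace(x), dp, noise_sd=1.0)
        b = detect_spikes(RawTrace(np.r_[np.zeros(shift), x]), dp, noise_sd=1.0)
        np.testing.assert_allclose(b.train.times_s - shift / 10_000.0,
                                   a.train.times_s, atol=1e-12)

    def test_scaling_trace_and_threshold_invariant(self, rng):
        dp = DetectionParams()
        x = rng.normal(0, 1.0, 50000)
        a = detect_spikes(RawTrace(x), dp, noise_sd=1.0)
        b = detect_spikes(RawTrace(7.0 * x), dp, noise_sd=7.0)
        assert np.array_equal(a.train.times_s, b.train.times_s)

    def test_boundary_cutout_padded_and_flagged(self):
        x = np.zeros(20000)
        x[3] = -8.0
        res = detect_spikes(RawTrace(x), DetectionParams(), noise_sd=1.0)
        assert len(res.train) == 1 and res.padded[0]
        assert res.cutouts.shape[1] == 30  # 1 ms pre + 2 ms post at 10 kHz


class TestPSTH:
    def test_empty_train_all_zero(self):
        psth = compute_psth(SpikeTrain("c", []), 0.5, (0.0, 10.0))
        assert np.all(psth.rates == 0.0) and psth.rates.size == 20

    def test_three_spikes_one_bin(self):
        psth = compute_psth(SpikeTrain("c", [0.1, 0.2, 0.3]), 1.0, (0.0, 1.0))
        assert psth.rates.tolist() == [3.0]

    def test_count_conservation_random_trains(self, rng):
        for _ in range(5):
            times = np.sort(rng.uniform(0, 30, 200))
            times = np.unique(times)
            psth = compute_psth(SpikeTrain("c", times), 0.25, (0.0, 30.0))
            n_in = np.count_nonzero((times >= 0) & (times < 30.0))
            assert psth.rates.sum() * psth.bin_s == pytest.approx(n_in)


class TestExtractResponse:
    def test_flat_baseline_no_response(self):
        psth = PSTH(bin_s=1.0, rates=np.full(30, 1.0), t0=0.0)
        base = BaselineStats(1.0, 0.5, (0.0, 3.0))
        m = extract_response(psth, base, stim_onset_s=3.0)
        assert not m.responded and m.duration_s == 0.0

    def test_hand_computed_latency_and_duration(self):
        """Baseline 1 +/- 0.5 Hz, 10 Hz spanning bins [5, 20), stimulus at
        bin 3, m=2, gap=2: latency 2 s, duration 15 s."""
        rates = np.full(30, 1.0)
        rates[5:20] = 10.0
        psth = PSTH(bin_s=1.0, rates=rates, t0=0.0)
        base = BaselineStats(1.0, 0.5, (0.0, 3.0))
        m = extract_response(psth, base, stim_onset_s=3.0,
                             m_onset_bins=2, gap_bins=2)
        assert m.responded
        assert m.onset_latency_s == pytest.approx(2.0)
        assert m.duration_s == pytest.approx(15.0)

    def test_gap_tolerance_bridges_short_dips(self):
        rates = np.full(40, 0.0)
        rates[5:15] = 10.0
        rates[17:25] = 10.0       # 2-bin dip bridged when gap_bins >= 2
        psth = PSTH(bin_s=1.0, rates=rates, t0=0.0)
        base = BaselineStats(0.0, 1.0, (0.0, 5.0))
        bridged = extract_response(psth, base, 5.0, gap_bins=2)
        split = extract_response(psth, base, 5.0, gap_bins=1)
        assert bridged.duration_s == pytest.approx(20.0)
        assert split.duration_s == pytest.approx(10.0)

    def test_adding_spikes_inside_window_never_shrinks_response(self, rng):
        rates = np.full(40, 0.0)
        rates[5:15] = 8.0
        psth = PSTH(bin_s=1.0, rates=rates, t0=0.0)
        base = BaselineStats(0.0, 1.0, (0.0, 5.0))
        m0 = extract_response(psth, base, 5.0)
        rates2 = rates.copy()
        rates2[8:12] += 5.0
        m1 = extract_response(PSTH(1.0, rates2, 0.0), base, 5.0)
        assert m1.duration_s >= m0.duration_s

    def test_zero_baseline_sd_uses_floor_and_flags(self):
        rates = np.full(20, 0.0)
        rates[5:10] = 10.0
        psth = PSTH(bin_s=1.0, rates=rates, t0=0.0)
        base = BaselineStats(0.0, 0.0, (0.0, 5.0))
        m = extract_response(psth, base, 5.0, sd_floor_hz=1.0)
        assert m.sd_floored and m.responded
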