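import numpy as np
import pandas as pd
import pytest

from melanocycle.adaptation import (adaptation_rate, build_lram,
                                    classify_latency, cluster_subtypes,
                                    compare_adaptation, fit_repetition_trend,
                                    sensitivity_distribution)
from melanocycle.errors import InputError


def make_table(values_by_duration, n_cells=1, metric="duration_s"):
    """Repetition table where every cell carries the given per-duration
    repetition series (plus optional per-cell offsets)."""
    rows = []
    for c in range(n_cells):
        for dur, vals in values_by_duration.items():
            for rep, v in enumerate(vals, start=1):
                rows.append({"cell_id": f"c{c}", "stimulus_duration_s": dur,
                             "repetition_index": rep, metric: v})
    return pd.DataFrame(rows)


class TestOLS:
    def test_exact_line(self):
        slope, intercept, fitted = fit_repetition_trend([10, 8, 6, 4, 2])
        assert slope == pytest.approx(-2.0)
        assert intercept == pytest.approx(12.0)
        assert np.allclose(fitted, [10, 8, 6, 4, 2])

    def test_constant_series(self):
        slope, intercept, _ = fit_repetition_trend([7, 7, 7, 7, 7])
        assert slope == 0.0 and intercept == 7.0

    def test_matches_normal_equations_oracle(self, rng):
        """20 seeded noisy lines against an explicit (X'X)^-1 X'y solve."""
        for _ in range(20):
            y = rng.normal(5, 2, 5) + rng.normal(0, 1) * np.arange(5)
            X = np.column_stack([np.arange(1, 6), np.ones(5)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            slope, intercept, _ = fit_repetition_trend(y)
            assert abs(slope - beta[0]) < 1e-10
            assert abs(intercept - beta[1]) < 1e-10

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            fit_repetition_trend([1.0])


class TestLRAM:
    def test_flat_table_flat_surface(self):
        tab = make_table({d: [5.0] * 5 for d in (0.1, 1.0, 10.0, 60.0)})
        grid = build_lram(tab)
        assert np.allclose(grid.z, 5.0)

    def test_grid_nodes_reproduce_fitted_values_exactly(self):
        tab = make_table({0.1: [1, 2, 3, 4, 5], 1.0: [10, 8, 6, 4, 2],
                          10.0: [20, 20, 20, 20, 20], 60.0: [50, 45, 40, 35, 30]})
        grid = build_lram(tab)
        for d_i, dur in enumerate(grid.durations_s):
            xi = np.searchsorted(grid.x, np.log10(dur))
            for r_i, rep in enumerate(range(1, 6)):
                yi = np.searchsorted(grid.y, rep)
                assert grid.z[xi, yi] == grid.fitted[d_i, r_i]

    def test_adapting_population_differs_at_long_durations_late_reps(self):
        """A strongly adapting profile (steep negative slopes at 10/60 s)
        versus a resistant one: the surface deficit concentrates at long
        stimuli x late repetitions."""
        resistant = make_table({0.1: [2] * 5, 1.0: [8] * 5,
                                10.0: [30, 29, 29, 28, 28],
                                60.0: [60, 59, 58, 58, 57]})
        adapting = make_table({0.1: [2] * 5, 1.0: [8, 7, 7, 6, 6],
                               10.0: [30, 22, 15, 9, 4],
                               60.0: [60, 40, 25, 12, 3]})
        diff = build_lram(resistant).z - build_lram(adapting).z
        late_long = diff[-10:, -10:].mean()
        early_short = diff[:10, :10].mean()
        assert late_long > 20 > early_short
        assert early_short < 3

    def test_missing_duration_errors(self):
        tab = make_table({0.1: [1] * 5, 1.0: [1] * 5, 10.0: [1] * 5})
        with pytest.raises(InputError, match="60"):
            build_lram(tab)


class TestAdaptationRate:
    def test_constant_cells_zero_slope(self):
        tab = make_table({60.0: [7, 7, 7, 7, 7]}, n_cells=10)
        stats = adaptation_rate(tab)
        assert stats.mean_slope == 0.0
        assert stats.p_slope_vs_zero == pytest.approx(1.0)
        assert stats.n_cells == 10

    def test_shift_invariance_and_scale_equivariance(self, rng):
        base = {60.0: list(rng.normal(30, 2, 5))}
        tab = make_table(base, n_cells=6)
        s0 = adaptation_rate(tab)
        shifted = tab.assign(duration_s=tab.duration_s + 100.0)
        assert adaptation_rate(shifted).mean_slope == pytest.approx(s0.mean_slope)
        scaled = tab.assign(duration_s=tab.duration_s * 3.0)
        assert adaptation_rate(scaled).mean_slope == pytest.approx(3 * s0.mean_slope)

    def test_incomplete_cells_excluded_and_logged(self):
        tab = make_table({60.0: [5, 4, 3, 2, 1]}, n_cells=3)
        tab = tab[~((tab.cell_id == "c1") & (tab.repetition_index == 5))]
        stats = adaptation_rate(tab)
        assert stats.n_cells == 2
        assert stats.excluded_cells == ["c1"]

    def test_group_comparison_detects_difference(self, rng):
        a = make_table({60.0: [30, 28, 26, 24, 22]}, n_cells=8)
        a["duration_s"] += rng.normal(0, 0.5, len(a))
        b = make_table({60.0: [30, 30, 30, 30, 30]}, n_cells=8)
        b["duration_s"] += rng.normal(0, 0.5, len(b))
        _, p = compare_adaptation(adaptation_rate(a), adaptation_rate(b))
        assert p < 0.01


class TestClustering:
    def _archetypes(self, n=20, rng=None):
        rng = rng or np.random.default_rng(0)
        t = np.arange(120.0)
        sustained = np.exp(-t / 200.0)
        transient = np.exp(-t / 5.0)
        feats, durations = [], []
        for i in range(n):
            if i % 2 == 0:
                feats.append(sustained + rng.normal(0, 0.02, t.size))
                durations.append(100.0)
            else:
                feats.append(transient + rng.normal(0, 0.02, t.size))
                durations.append(8.0)
        return np.vstack(feats), np.asarray(durations)

    def test_separable_archetypes_perfectly_recovered(self):
        X, dur = self._archetypes()
        labels, centroids = cluster_subtypes(X, dur, seed=0)
        # label 0 = sustained (longer duration) by the relabeling contract
        assert np.array_equal(labels, np.arange(20) % 2)
        assert centroids.shape == (2, 120)

    def test_duplicated_cells_share_labels(self):
        X, dur = self._archetypes()
        X2, dur2 = np.vstack([X, X]), np.r_[dur, dur]
        labels = cluster_subtypes(X2, dur2, seed=0)[0]
        assert np.array_equal(labels[:20], labels[20:])

    def test_partition_invariant_to_input_order(self):
        X, dur = self._archetypes()
        perm = np.random.default_rng(3).permutation(20)
        labels = cluster_subtypes(X, dur, seed=0)[0]
        labels_p = cluster_subtypes(X[perm], dur[perm], seed=0)[0]
        assert np.array_equal(labels_p, labels[perm])

    def test_too_few_cells_errors(self):
        with pytest.raises(InputError):
            cluster_subtypes(np.ones((1, 4)), np.ones(1))


class TestLatencySplit:
    def test_bimodal_mixture_recovered(self, rng):
        lat = np.r_[rng.normal(1.0, 0.2, 30), rng.normal(30.0, 3.0, 10)]
        split = classify_latency(lat)
        assert 2.0 < split.threshold_s < 20.0
        assert split.prop_short == pytest.approx(0.75)
        assert split.prop_delayed == pytest.approx(0.25)

    def test_all_equal_degenerate(self):
        split = classify_latency(np.full(10, 2.0))
        assert split.degenerate and split.threshold_s is None
        assert split.prop_short == 1.0

    def test_scale_equivariant_proportions(self, rng):
        lat = np.r_[rng.normal(1.0, 0.2, 25), rng.normal(20.0, 2.0, 15)]
        a = classify_latency(lat)
        b = classify_latency(lat * 1000.0)   # e.g. seconds -> ms
        assert np.array_equal(a.labels, b.labels)
        assert b.threshold_s == pytest.approx(1000.0 * a.threshold_s)


class TestSensitivity:
    def _metrics(self):
        rows = []
        responses = {"c_all": {0.1: True, 1.0: True, 10.0: True, 60.0: True},
                     "c_60": {0.1: False, 1.0: False, 10.0: False, 60.0: True},
                     "c_none": {0.1: False, 1.0: False, 10.0: False, 60.0: False}}
        for cell, resp in responses.items():
            for dur, r in resp.items():
                rows.append({"cell_id": cell, "stimulus_duration_s": dur,
                             "responded": r})
        return pd.DataFrame(rows)

    def test_min_duration_and_never_responders(self):
        per_cell, hist = sensitivity_distribution(self._metrics())
        assert per_cell["c_all"] == 0.1
        assert per_cell["c_60"] == 60.0
        assert "c_none" not in per_cell.index
        assert hist["none"] == 1
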