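"""Adaptation analyses: repetition regressions, light-response adaptation
maps (LRAM), adaptation-rate statistics, subtype clustering and sensitivity.

The adaptation rate of a cell is the slope of the ordinary least-squares
regression of a response metric (duration or spike count) against the
repetition index of an identical stimulus.  An LRAM is the surface of
response duration over log10(stimulus duration) x repetition number built
from the per-duration regression fits with linear interpolation between
measured durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from sklearn.cluster import KMeans

from .errors import InputError

STANDARD_DURATIONS_S = (0.1, 1.0, 10.0, 60.0)
N_REPS = 5


def fit_repetition_trend(values: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Closed-form OLS of values against repetition index 1..k.

    Returns (slope, intercept, fitted values).  Requires k >= 2 finite
    values.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise InputError("need at least 2 repetitions for a trend")
    if not np.all(np.isfinite(y)):
        raise InputError("missing values in repetition series")
    x = np.arange(1, y.size + 1, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    intercept = float(ym - slope * xm)
    return slope, intercept, intercept + slope * x


@dataclass
class LRAMGrid:
    """Interpolated response-duration surface.

    ``x`` is log10(stimulus duration in s), ``y`` the repetition index, and
    ``z[i, j]`` the fitted duration at (x[i], y[j]).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    durations_s: np.ndarray = field(default_factory=lambda: np.array([]))
    fitted: np.ndarray = field(default_factory=lambda: np.array([[]]))

    def at(self, duration_s: float, repetition: float) -> float:
        interp = RegularGridInterpolator((self.x, self.y), self.z)
        return float(interp([[np.log10(duration_s), repetition]])[0])


def _grid_axis(log_durs: np.ndarray, n_points: int) -> np.ndarray:
    """Axis of ~n_points log-duration values that contains every measured
    duration as an exact node (no interpolation leakage at the data)."""
    spans = np.diff(log_durs)
    per = np.maximum(2, np.round(spans / spans.sum() * (n_points - 1)).astype(int))
    parts = [np.linspace(a, b, k + 1)[:-1]
             for a, b, k in zip(log_durs[:-1], log_durs[1:], per)]
    return np.unique(np.concatenate(parts + [log_durs]))


def build_lram(table: pd.DataFrame, metric: str = "duration_s",
               n_grid: int = 50, agg: str = "mean") -> LRAMGrid:
    """LRAM from a repetition table.

    The table needs columns cell_id, stimulus_duration_s, repetition_index
    and the metric.  Values are population-aggregated per (duration,
    repetition) (mean by default), each duration's repetition series is
    replaced by its OLS fit, and the fits are linearly interpolated across
    log10(duration) and repetition onto a regular grid whose nodes include
    the measured durations exactly.
    """
    need = {"stimulus_duration_s", "repetition_index", metric}
    if not need.issubset(table.columns):
        raise InputError(f"table lacks columns {sorted(need - set(table.columns))}")
    durs = np.sort(table["stimulus_duration_s"].unique())
    missing = set(STANDARD_DURATIONS_S) - {round(d, 9) for d in durs}
    if missing:
        raise InputError(f"missing stimulus durations: {sorted(missing)}")

    pivot = (table.groupby(["stimulus_duration_s", "repetition_index"])[metric]
             .agg(agg).unstack("repetition_index").sort_index())
    reps = np.asarray(pivot.columns, dtype=float)
    fitted = np.vstack([fit_repetition_trend(row)[2] for row in pivot.to_numpy()])

    log_durs = np.log10(np.asarray(pivot.index, dtype=float))
    x = _grid_axis(log_durs, n_grid)
    y = np.linspace(reps[0], reps[-1], n_grid)
    y = np.unique(np.concatenate([y, reps]))
    interp = RegularGridInterpolator((log_durs, reps), fitted, method="linear")
    xx, yy = np.meshgrid(x, y, indexing="ij")
    z = interp(np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    # pin the measured nodes to the fitted values (no interpolation leakage)
    ix = np.searchsorted(x, log_durs)
    iy = np.searchsorted(y, reps)
    z[np.ix_(ix, iy)] = fitted
    return LRAMGrid(x=x, y=y, z=z, durations_s=10.0 ** log_durs, fitted=fitted)


@dataclass
class AdaptationStats:
    per_cell_slopes: np.ndarray
    mean_slope: float
    sem_slope: float
    p_slope_vs_zero: float
    n_cells: int
    excluded_cells: list[str] = field(default_factory=list)


def adaptation_rate(table: pd.DataFrame, metric: str = "duration_s",
                    stimulus_duration_s: float = 60.0,
                    n_reps: int = N_REPS) -> AdaptationStats:
    """Per-cell OLS slope across repetitions of the 1-min stimulus, with
    population mean +/- SEM and a one-sample t test of the slopes against 0.

    Cells with fewer than ``n_reps`` repetitions are excluded and reported.
    """
    sub = table[np.isclose(table["stimulus_duration_s"], stimulus_duration_s)]
    slopes, excluded = [], []
    for cell, grp in sub.groupby("cell_id", sort=True):
        grp = grp.sort_values("repetition_index")
        if len(grp) < n_reps or grp["repetition_index"].iloc[-1] != n_reps:
            excluded.append(str(cell))
            continue
        slopes.append(fit_repetition_trend(grp[metric].to_numpy()[:n_reps])[0])
    slopes = np.asarray(slopes)
    if slopes.size == 0:
        raise InputError("no cell has a complete repetition series")
    if slopes.size > 1 and np.ptp(slopes) > 0:
        p = float(stats.ttest_1samp(slopes, 0.0).pvalue)
    else:
        p = 1.0
    sem = float(slopes.std(ddof=1) / np.sqrt(slopes.size)) if slopes.size > 1 else 0.0
    return AdaptationStats(per_cell_slopes=slopes, mean_slope=float(slopes.mean()),
                           sem_slope=sem, p_slope_vs_zero=p,
                           n_cells=int(slopes.size), excluded_cells=excluded)


def compare_adaptation(a: AdaptationStats, b: AdaptationStats,
                       alternative: str = "two-sided") -> tuple[float, float]:
    """Welch two-sample t test between the per-cell slopes of two groups."""
    res = stats.ttest_ind(a.per_cell_slopes, b.per_cell_slopes,
                          equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Subtype clustering and latency classification
# ---------------------------------------------------------------------------

def cluster_subtypes(features: np.ndarray, response_durations: np.ndarray,
                     k: int = 2, seed: int = 0,
                     n_init: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """K-means partition of per-cell response profiles.

    ``features`` is (n_cells, n_features), typically max-normalized binned
    1-min responses.  Clusters are relabeled deterministically by descending
    median response duration (label 0 = most sustained).  Rows are fitted in
    a canonical (lexicographic) order so the partition is invariant to input
    ordering.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < k:
        raise InputError(f"need at least k={k} cells, got {X.shape[0]}")
    order = np.lexsort(X.T[::-1])  # canonical row order
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = np.empty(X.shape[0], dtype=int)
    raw[order] = km.fit_predict(X[order])
    durations = np.asarray(response_durations, dtype=float)
    medians = np.array([np.median(durations[raw == c]) for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[np.argsort(-medians)] = np.arange(k)
    labels = relabel[raw]
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    return labels, centroids


def normalized_response_features(trains, stim_onset_s: float,
                                 window_s: float = 120.0,
                                 bin_s: float = 1.0) -> np.ndarray:
    """Per-cell binned rates over [stim onset, onset + window], each cell
    scaled by its own maximum (flat cells stay zero)."""
    edges = stim_onset_s + np.arange(0, window_s + bin_s, bin_s)
    feats = []
    for tr in trains:
        counts, _ = np.histogram(tr.times_s, bins=edges)
        rates = counts / bin_s
        m = rates.max()
        feats.append(rates / m if m > 0 else rates)
    return np.vstack(feats)


@dataclass
class LatencySplit:
    labels: np.ndarray            # 0 = short, 1 = delayed
    threshold_s: float | None
    prop_short: float
    prop_delayed: float
    degenerate: bool


def classify_latency(latencies: np.ndarray) -> LatencySplit:
    """Two-class 1-D split minimizing within-class variance (Otsu-style).

    All-equal input returns a single class with the ``degenerate`` flag.
    The split is equivariant to rescaling of the latency unit.
    """
    lat = np.asarray(latencies, dtype=float)
    lat = lat[np.isfinite(lat)]
    if lat.size == 0:
        raise InputError("no finite latencies to classify")
    srt = np.sort(lat)
    if srt[0] == srt[-1]:
        return LatencySplit(np.zeros(lat.size, dtype=int), None, 1.0, 0.0, True)
    best, best_thr = np.inf, None
    for i in range(1, srt.size):
        if srt[i] == srt[i - 1]:
            continue
        left, right = srt[:i], srt[i:]
        w = left.size * left.var() + right.size * right.var()
        if w < best:
            best, best_thr = w, 0.5 * (srt[i - 1] + srt[i])
    labels = (lat > best_thr).astype(int)
    return LatencySplit(labels, float(best_thr),
                        float(np.mean(labels == 0)), float(np.mean(labels == 1)),
                        False)


def sensitivity_distribution(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Shortest stimulus duration evoking a response, per cell.

    Returns (per-cell minimum duration, histogram over durations); cells
    never responding are reported under the key ``"none"`` of the histogram
    and excluded from the per-cell series.
    """
    responders = table[table["responded"].astype(bool)]
    min_dur = responders.groupby("cell_id")["stimulus_duration_s"].min()
    all_cells = table["cell_id"].unique()
    n_never = len(set(all_cells) - set(min_dur.index))
    hist = min_dur.value_counts().sort_index()
    hist.index = [str(v) for v in hist.index]
    if n_never:
        hist = pd.concat([hist, pd.Series({"none": n_never})])
    return min_dur, hist
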