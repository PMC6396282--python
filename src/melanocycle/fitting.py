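"""Recovery of effective photocycle rates from population firing.

Given the population-averaged peristimulus rate of a simulated (or recorded)
population under a known protocol, the two genotype-resolved rates that the
knockout experiments isolate — the effective deactivation rate
k_deact2 * arr2_level and the effective regeneration rate
k_regen1 * arr1_level — are estimated by nonlinear least squares against the
deterministic forward model (photocycle -> drive -> rate).  Deactivation is
constrained by the post-light decay of firing; regeneration by the response
to a subsequent pulse after a dark gap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .params import GenotypeConfig, PhotocycleParams, TransductionParams
from .photocycle import simulate_photocycle
from .population import PopulationResult
from .protocols import LightProtocol, protocol_single_pulse, LightSegment, LightProtocol as _LP
from .transduction import drive_to_rate


def recovery_protocol(irradiance: float = 5e12) -> LightProtocol:
    """Two 60-s pulses separated by 30 s of darkness: the post-OFF decay of
    the first pulse pins deactivation, while the partial recovery of the
    second response (the gap is short relative to the regeneration time
    constant) pins regeneration."""
    segs = [LightSegment(60.0, 60.0, irradiance),
            LightSegment(150.0, 60.0, irradiance)]
    return _LP(segs, total_duration_s=330.0, name="recovery_protocol")


def population_mean_rate(pop: PopulationResult, bin_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Population-mean PSTH (Hz) from the spike trains."""
    T = pop.photocycle.t[-1]
    edges = np.arange(0.0, T + bin_s, bin_s)
    counts = np.zeros(edges.size - 1)
    for tr in pop.trains:
        c, _ = np.histogram(tr.times_s, bins=edges)
        counts += c
    rate = counts / (bin_s * pop.n_cells)
    return 0.5 * (edges[:-1] + edges[1:]), rate


def _hetero_quantiles(cv: float, n_q: int) -> np.ndarray:
    """Representative unit-mean lognormal values at equal-mass quantiles."""
    if cv == 0:
        return np.ones(1)
    from scipy import stats
    sigma2 = np.log1p(cv ** 2)
    q = (np.arange(n_q) + 0.5) / n_q
    return np.exp(stats.norm.ppf(q) * np.sqrt(sigma2) - sigma2 / 2.0)


def _forward_mean_rate(k_d2: float, k_r1: float, protocol: LightProtocol,
                       params: PhotocycleParams, tp: TransductionParams,
                       centers: np.ndarray, bin_s: float,
                       dt: float, dt_out: float,
                       cv_pigment: float = 0.0, cv_threshold: float = 0.0,
                       n_q: int = 5) -> np.ndarray:
    """Deterministic population-mean rate at the PSTH bin centers for
    candidate effective rates.

    Cross-redundancy rates are folded into the candidates (the data only
    constrain the total effective rates), so the fit genotype carries them
    as zero.  Heterogeneity is handled by averaging the rate nonlinearity
    over equal-mass quantiles of the lognormal pigment and threshold
    distributions (the fit knows the population model, not the per-cell
    draws)."""
    p = replace(params, k_deact2=k_d2, k_regen1=k_r1,
                k_deact_cross=0.0, k_regen_cross=0.0)
    g = GenotypeConfig(name="fit")
    pc = simulate_photocycle(protocol, p, g, dt=dt, dt_out=dt_out, tp=tp)
    scales = _hetero_quantiles(cv_pigment, n_q)
    thetas = tp.theta * _hetero_quantiles(cv_threshold, n_q)
    rate = np.zeros_like(pc.drive)
    for s in scales:
        for th in thetas:
            rate += drive_to_rate(s * pc.drive, dt_out, tp, theta=th)
    rate /= scales.size * thetas.size
    # average the model rate within each PSTH bin
    n_per = max(1, int(round(bin_s / dt_out)))
    n_bins = centers.size
    usable = rate[:n_bins * n_per]
    return usable.reshape(n_bins, n_per).mean(axis=1)


@dataclass
class RecoveryResult:
    k_deact2_eff: float
    k_regen1_eff: float
    cost: float
    success: bool


def recover_rates(pop: PopulationResult,
                  params: PhotocycleParams | None = None,
                  tp: TransductionParams | None = None,
                  protocol: LightProtocol | None = None,
                  bin_s: float = 0.5, dt: float = 1e-3,
                  dt_out: float = 0.01,
                  x0: tuple[float, float] = (0.05, 0.02)) -> RecoveryResult:
    """Least-squares fit of (k_deact2*arr2, k_regen1*arr1) to the population
    mean PSTH.  Other kinetic and transduction parameters and the
    heterogeneity CVs are taken as known.  The fit is performed in log-rate
    space with broad bounds."""
    params = params or PhotocycleParams()
    tp = tp or TransductionParams()
    protocol = protocol or recovery_protocol()
    centers, observed = population_mean_rate(pop, bin_s)
    cv_p = pop.meta.get("pop", {}).get("cv_pigment", 0.0)
    cv_t = pop.meta.get("pop", {}).get("cv_threshold", 0.0)

    def residuals(logx):
        k_d2, k_r1 = np.exp(logx)
        model = _forward_mean_rate(k_d2, k_r1, protocol, params, tp,
                                   centers, bin_s, dt, dt_out,
                                   cv_pigment=cv_p, cv_threshold=cv_t)
        return model - observed

    res = least_squares(residuals, np.log(np.asarray(x0)),
                        bounds=(np.log([1e-4, 1e-4]), np.log([5.0, 5.0])),
                        xtol=1e-10, ftol=1e-10)
    k_d2, k_r1 = np.exp(res.x)
    return RecoveryResult(float(k_d2), float(k_r1), float(res.cost),
                          bool(res.success))
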