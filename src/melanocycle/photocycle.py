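"""Five-state melanopsin photocycle as a linear ODE with piecewise-constant
photon flux.

State vector (fractions of the total pigment pool, summing to one):

    [dark, active, phospho_active, arr_bound, spent]

Within each interval of constant flux the system ``x' = A x`` has a constant
rate matrix, so integration proceeds with a classical 4th-order Runge-Kutta
scheme whose one-step update for a linear system is the constant matrix

    M = I + hA + (hA)^2/2 + (hA)^3/6 + (hA)^4/24,

applied repeatedly at the internal step ``dt`` (default 1 ms).  States are
stored every ``stride`` internal steps, with a conservation renormalization
guard at each stored point.  Supplementation events are instantaneous pool
transfers applied between intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, StabilityError
from .params import GenotypeConfig, PhotocycleParams, TransductionParams
from .protocols import LightProtocol

STATE_NAMES = ("dark", "active", "phospho_active", "arr_bound", "spent")
DARK, ACTIVE, PHOSPHO, ARR_BOUND, SPENT = range(5)


def rate_matrix(params: PhotocycleParams, genotype: GenotypeConfig,
                phi: float) -> np.ndarray:
    """Rate matrix A (columns sum to zero) for photon flux ``phi``."""
    a = params.sigma_act * phi
    kd2 = genotype.k_d2eff(params)
    kr1 = genotype.k_r1eff(params)
    ks = params.k_spont
    kt = params.k_turnover + genotype.retinal_supply_rate
    A = np.zeros((5, 5))
    A[DARK, DARK] = -a
    A[ACTIVE, DARK] = a
    A[ACTIVE, ACTIVE] = -(params.k_phos + ks)
    A[PHOSPHO, ACTIVE] = params.k_phos
    A[PHOSPHO, PHOSPHO] = -(kd2 + ks)
    A[ARR_BOUND, PHOSPHO] = kd2
    A[ARR_BOUND, ARR_BOUND] = -kr1
    A[DARK, ARR_BOUND] = kr1
    A[SPENT, ACTIVE] = ks
    A[SPENT, PHOSPHO] = ks
    A[SPENT, SPENT] = -kt
    A[DARK, SPENT] = kt
    return A


def _rk4_step_matrix(A: np.ndarray, h: float) -> np.ndarray:
    hA = h * A
    M = np.eye(5) + hA
    term = hA
    for k in (2.0, 3.0, 4.0):
        term = term @ hA / k
        M = M + term
    return M


def drive_from_states(states: np.ndarray, tp: TransductionParams,
                      pigment_scale: float = 1.0) -> np.ndarray:
    """Instantaneous signaling drive D(t) from a state trajectory."""
    return pigment_scale * tp.gain * (
        states[:, ACTIVE] + tp.eps_phospho * states[:, PHOSPHO]
    )


@dataclass
class PhotocycleResult:
    """Trajectory of pigment-state fractions plus the signaling drive."""

    t: np.ndarray                 # stored time points, seconds
    states: np.ndarray            # (len(t), 5) fractions
    drive: np.ndarray             # dimensionless drive D(t)
    dt: float                     # storage resolution, seconds
    meta: dict = field(default_factory=dict)

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def drive_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.drive)


def simulate_photocycle(
    protocol: LightProtocol,
    params: PhotocycleParams | None = None,
    genotype: GenotypeConfig | None = None,
    dt: float = 1e-3,
    dt_out: float | None = None,
    tp: TransductionParams | None = None,
    initial_state: np.ndarray | None = None,
) -> PhotocycleResult:
    """Integrate the photocycle over a protocol.

    ``dt`` is the internal RK4 step; ``dt_out`` (a multiple of ``dt``,
    default equal to it) is the storage resolution.  Mass conservation is
    enforced to solver tolerance by a renormalization guard at every stored
    step.  Raises :class:`StabilityError` when ``dt`` exceeds one tenth of
    the fastest kinetic timescale.
    """
    params = params or PhotocycleParams()
    genotype = genotype or GenotypeConfig()
    tp = tp or TransductionParams()
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    dt_out = dt if dt_out is None else dt_out
    stride = int(round(dt_out / dt))
    if stride < 1 or abs(stride * dt - dt_out) > 1e-9 * max(1.0, dt_out):
        raise ConfigurationError("dt_out must be a positive multiple of dt")

    phi_max = max((s.irradiance for s in protocol.segments), default=0.0)
    rates = [params.sigma_act * phi_max, params.k_phos,
             genotype.k_d2eff(params) + params.k_spont,
             genotype.k_r1eff(params),
             params.k_turnover + genotype.retinal_supply_rate]
    fastest = max((r for r in rates if r > 0), default=0.0)
    if fastest > 0 and dt > 0.1 / fastest:
        raise StabilityError(
            f"dt={dt:g} s too coarse for fastest rate {fastest:g} s^-1; "
            f"use dt <= {0.1 / fastest:g} s"
        )

    # breakpoints: flux changes and supplementation events
    events = {round(t / dt) for t, _ in genotype.supplementation_events
              if 0.0 <= t <= protocol.total_duration_s}
    bp_steps = sorted({round(b / dt) for b in protocol.breakpoints()} | events)
    n_total = round(protocol.total_duration_s / dt)
    if bp_steps[-1] != n_total:
        bp_steps.append(n_total)

    supp_by_step: dict[int, float] = {}
    for t_ev, rho in genotype.supplementation_events:
        k = round(t_ev / dt)
        if 0 <= k <= n_total:
            # compose multiple events at the same step
            prev = supp_by_step.get(k, 0.0)
            supp_by_step[k] = 1.0 - (1.0 - prev) * (1.0 - rho)

    x = np.array([1.0, 0.0, 0.0, 0.0, 0.0]) if initial_state is None \
        else np.asarray(initial_state, dtype=float).copy()
    if x.shape != (5,) or np.any(x < -1e-12) or abs(x.sum() - 1.0) > 1e-6:
        raise ConfigurationError("initial_state must be 5 non-negative "
                                 "fractions summing to 1")

    n_out = n_total // stride + 1
    states = np.empty((n_out, 5))
    states[0] = x
    out_idx = 1

    step = 0
    for b_start, b_end in zip(bp_steps[:-1], bp_steps[1:]):
        if b_start in supp_by_step:
            rho = supp_by_step[b_start]
            transfer = rho * (x[ARR_BOUND] + x[SPENT])
            x[DARK] += transfer
            x[ARR_BOUND] *= 1.0 - rho
            x[SPENT] *= 1.0 - rho
        t_mid = (b_start + 0.5) * dt
        phi = float(protocol.irradiance_at(np.array([t_mid]))[0])
        A = rate_matrix(params, genotype, phi)
        M1 = _rk4_step_matrix(A, dt)
        Mk = np.linalg.matrix_power(M1, stride) if stride > 1 else M1
        n_steps = b_end - b_start
        pos = 0
        while pos < n_steps:
            k = min(stride - (step % stride), n_steps - pos)
            if k == stride:
                x = Mk @ x
            else:
                for _ in range(k):
                    x = M1 @ x
            step += k
            pos += k
            if step % stride == 0:
                np.clip(x, 0.0, None, out=x)
                x /= x.sum()
                states[out_idx] = x
                out_idx += 1

    states = states[:out_idx]
    t = np.arange(out_idx) * dt_out
    drive = drive_from_states(states, tp)
    meta = {
        "protocol": protocol.to_dict(),
        "genotype": genotype.to_dict(),
        "params": params.to_dict(),
        "transduction": tp.to_dict(),
        "dt": dt,
        "dt_out": dt_out,
    }
    return PhotocycleResult(t=t, states=states, drive=drive, dt=dt_out, meta=meta)


def steady_state(params: PhotocycleParams, genotype: GenotypeConfig,
                 phi: float) -> np.ndarray:
    """Steady-state fractions under constant flux: the normalized null space
    of the rate matrix, obtained by replacing one balance equation with the
    conservation constraint."""
    A = rate_matrix(params, genotype, phi)
    B = A.copy()
    B[0, :] = 1.0
    b = np.zeros(5)
    b[0] = 1.0
    return np.linalg.solve(B, b)
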